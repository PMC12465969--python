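"""DNM filter cascade, read-level check, and callable accounting."""

import numpy as np
import pytest

from canidnm.calling import (
    apply_dnm_filters,
    compute_callable_profile,
    exclude_low_depth_trios,
    read_check,
    site_is_callable,
)
from canidnm.records import CandidateSite, TrioRecord
from canidnm.simulate import simulate_site_evidence


def make_site(**overrides):
    base = dict(
        contig="A1",
        pos=1000,
        ref="C",
        alt="T",
        gt={"offspring": (0, 1), "sire": (0, 0), "dam": (0, 0)},
        gq={"offspring": 45, "sire": 50, "dam": 50},
        dp={"offspring": 40, "sire": 40, "dam": 40},
        ad={"offspring": (20, 20), "sire": (40, 0), "dam": (39, 1)},
        context3="ACT",
    )
    base.update(overrides)
    return CandidateSite(**base)


@pytest.fixture
def auto_trio():
    return TrioRecord(
        trio_id="T1", offspring_id="O1", sire_id="S1", dam_id="D1",
        offspring_sex="F", paternal_age_years=5, maternal_age_years=4,
        mean_depth={"offspring": 43.3, "sire": 43.3, "dam": 43.3},
    )


class TestFilterCascade:
    def test_clean_autosomal_site_passes(self, auto_trio):
        v = apply_dnm_filters(make_site(), auto_trio)
        assert v.passed and v.failed_rules == []

    def test_two_parent_alt_reads_fail(self, auto_trio):
        v = apply_dnm_filters(make_site(ad={"offspring": (20, 20), "sire": (38, 2),
                                            "dam": (40, 0)}), auto_trio)
        assert not v.passed and "PARENT_ALT_READS" in v.failed_rules

    def test_one_alt_read_across_parents_allowed(self, auto_trio):
        v = apply_dnm_filters(make_site(ad={"offspring": (20, 20), "sire": (39, 1),
                                            "dam": (40, 0)}), auto_trio)
        assert v.passed

    def test_low_gq_fails(self, auto_trio):
        v = apply_dnm_filters(make_site(gq={"offspring": 39, "sire": 50, "dam": 50}),
                              auto_trio)
        assert "GQ" in v.failed_rules
        # boundary: GQ = 40 inclusive
        assert apply_dnm_filters(
            make_site(gq={"offspring": 40, "sire": 50, "dam": 50}), auto_trio
        ).passed

    @pytest.mark.parametrize("dp, ok", [(11, False), (12, True), (86, True), (87, False)])
    def test_depth_bounds(self, auto_trio, dp, ok):
        # indDP 43.3: need DP >= 12, 21.65 < DP < 86.6 -> 12 fails mean-low
        expect = ok and dp > 21.65
        v = apply_dnm_filters(
            make_site(dp={"offspring": dp, "sire": 40, "dam": 40},
                      ad={"offspring": (dp // 2, dp - dp // 2), "sire": (40, 0),
                          "dam": (40, 0)}),
            auto_trio,
        )
        assert v.passed == expect

    # bounds are strict: AB = 0.25 and AB = 0.75 both fail
    @pytest.mark.parametrize("ab_alt, total, ok", [(11, 40, True), (10, 40, False),
                                                   (30, 40, False), (5, 30, False)])
    def test_allele_balance_strict_bounds(self, auto_trio, ab_alt, total, ok):
        v = apply_dnm_filters(
            make_site(ad={"offspring": (total - ab_alt, ab_alt), "sire": (40, 0),
                          "dam": (40, 0)}),
            auto_trio,
        )
        assert v.passed == ok

    def test_male_x_unique_halved_thresholds(self, region_map):
        """X-unique site in a male offspring: depth thresholds halved
        (DP >= 6 and 6 < DP < 24 at indDP 24), allele balance > 0.75."""
        trio = TrioRecord(
            trio_id="T1", offspring_id="O1", sire_id="S1", dam_id="D1",
            offspring_sex="M", paternal_age_years=5, maternal_age_years=4,
            mean_depth={"offspring": 24.0, "sire": 24.0, "dam": 24.0},
        )
        site = make_site(
            contig="X", pos=100_000_000,  # beyond the 6.8-Mb PAR
            dp={"offspring": 7, "sire": 7, "dam": 7},
            ad={"offspring": (0, 7), "sire": (7, 0), "dam": (7, 0)},
        )
        v = apply_dnm_filters(site, trio, region_map)
        assert v.passed, v.failed_rules
        # same site with autosomal thresholds would fail on depth
        v_auto = apply_dnm_filters(
            make_site(dp={"offspring": 7, "sire": 7, "dam": 7},
                      ad={"offspring": (0, 7), "sire": (7, 0), "dam": (7, 0)}),
            trio,
        )
        assert "DEPTH" in v_auto.failed_rules

    def test_male_par_site_treated_as_autosomal(self, region_map):
        trio = TrioRecord(
            trio_id="T1", offspring_id="O1", sire_id="S1", dam_id="D1",
            offspring_sex="M", paternal_age_years=5, maternal_age_years=4,
            mean_depth={"offspring": 43.3, "sire": 43.3, "dam": 43.3},
        )
        v = apply_dnm_filters(make_site(contig="X", pos=5), trio, region_map)
        assert v.passed  # AB 0.5 acceptable inside the PAR

    def test_non_snv_fails(self, auto_trio):
        v = apply_dnm_filters(make_site(alt="TT"), auto_trio)
        assert "NOT_SNV" in v.failed_rules

    def test_inherited_het_fails_gt_pattern(self, auto_trio):
        v = apply_dnm_filters(
            make_site(gt={"offspring": (0, 1), "sire": (0, 1), "dam": (0, 0)},
                      ad={"offspring": (20, 20), "sire": (20, 20), "dam": (40, 0)}),
            auto_trio,
        )
        assert "GT_PATTERN" in v.failed_rules

    def test_missing_ad_fails_closed(self, auto_trio):
        v = apply_dnm_filters(make_site(ad={"offspring": (20, 20), "sire": None,
                                            "dam": (40, 0)}), auto_trio)
        assert v.failed_rules == ["MISSING_EVIDENCE"]

    def test_verdict_lists_all_violations(self, auto_trio):
        """Rules are evaluated independently, so the outcome cannot
        depend on evaluation order."""
        v = apply_dnm_filters(
            make_site(gq={"offspring": 10, "sire": 50, "dam": 50},
                      ad={"offspring": (38, 2), "sire": (30, 10), "dam": (40, 0)}),
            auto_trio,
        )
        assert set(v.failed_rules) == {"GQ", "PARENT_ALT_READS", "ALLELE_BALANCE"}


class TestReadCheck:
    def test_clean_reads_pass(self):
        assert read_check(["T"] * 12 + ["C"] * 18, ["C"] * 30, ["C"] * 30, "C", "T")

    def test_two_incorrect_parent_reads_fail(self):
        assert not read_check(["T"] * 12 + ["C"] * 18, ["C"] * 28 + ["T", "T"],
                              ["C"] * 30, "C", "T")

    def test_one_incorrect_read_allowed(self):
        assert read_check(["T"] * 12 + ["C"] * 18, ["C"] * 29 + ["T"], ["C"] * 30,
                          "C", "T")

    def test_low_read_ab_fails(self):
        assert not read_check(["T"] * 5 + ["C"] * 25, ["C"] * 30, ["C"] * 30, "C", "T")

    def test_third_allele_in_offspring_counts_incorrect(self):
        reads = ["T"] * 12 + ["C"] * 16 + ["G", "G"]
        assert not read_check(reads, ["C"] * 30, ["C"] * 30, "C", "T")

    def test_no_reads_fails_closed(self):
        assert not read_check([], ["C"] * 30, ["C"] * 30, "C", "T")


class TestCallable:
    def test_x_unique_scaling_by_sex(self, auto_trio):
        male = TrioRecord(
            trio_id="T2", offspring_id="O2", sire_id="S1", dam_id="D1",
            offspring_sex="M", paternal_age_years=5, maternal_age_years=4,
            mean_depth={"offspring": 40, "sire": 40, "dam": 40},
        )
        sites = {"AUTOSOME": 1000, "X_UNIQUE": 1000}
        pm = compute_callable_profile(sites, male)
        pf = compute_callable_profile(sites, auto_trio)  # female
        assert pm.callable_size["X_UNIQUE"] == 1000
        assert pf.callable_size["X_UNIQUE"] == 2000
        assert pm.callable_size["AUTOSOME"] == pf.callable_size["AUTOSOME"] == 2000

    def test_fully_covered_genome_fraction_one(self, region_map, auto_trio):
        sites = {lbl: region_map.span(lbl) for lbl in ("AUTOSOME", "PAR", "X_UNIQUE")}
        p = compute_callable_profile(sites, auto_trio, region_map.genome_size())
        assert p.callable_fraction == pytest.approx(1.0)

    def test_site_level_rules_match_filter_depth_rules(self, auto_trio):
        gts = {"sire": (0, 0), "dam": (0, 0)}
        assert site_is_callable(gts, {"offspring": 40, "sire": 40, "dam": 40}, auto_trio)
        assert not site_is_callable(gts, {"offspring": 11, "sire": 40, "dam": 40}, auto_trio)
        assert not site_is_callable({"sire": (0, 1), "dam": (0, 0)},
                                    {"offspring": 40, "sire": 40, "dam": 40}, auto_trio)

    def test_low_depth_trio_exclusion(self, auto_trio):
        low = TrioRecord(
            trio_id="T3", offspring_id="O3", sire_id="S1", dam_id="D1",
            offspring_sex="F", paternal_age_years=5, maternal_age_years=4,
            mean_depth={"offspring": 23.9, "sire": 40, "dam": 40},
        )
        assert exclude_low_depth_trios([auto_trio, low]) == [auto_trio]


class TestTruthRecovery:
    def test_noiseless_evidence_recovered_exactly(self, small_cohort):
        """With evidence noise off the cascade recovers every simulated
        DNM and rejects every inherited-heterozygote site."""
        ev = simulate_site_evidence(small_cohort, seed=5, noise=False,
                                    n_negative_per_trio=3)
        index = small_cohort.trio_index
        by_truth = {"dnm": [], "inherited": []}
        for tid, site, truth in ev:
            v = apply_dnm_filters(site, index[tid], small_cohort.region_map)
            by_truth[truth].append(v.passed)
        assert np.mean(by_truth["dnm"]) == 1.0
        assert np.mean(by_truth["inherited"]) == 0.0
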