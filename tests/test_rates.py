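"""Rate estimation, bootstrap CIs, composition correction, and the
closed-form X/PAR/recombination arithmetic."""

import numpy as np
import pytest

from canidnm.rates import (
    CompositionTable,
    bootstrap_rate,
    composition_corrected_rates,
    expected_x_autosome_ratio,
    mutation_rate,
    par_recombination_rates,
    phased_sex_ratio,
    recombination_mutagenesis,
)


class TestMutationRate:
    def test_zero_dnms(self):
        assert mutation_rate(0, 4.3e9) == 0.0

    def test_division(self):
        assert mutation_rate(21, 4.3e9) == pytest.approx(4.884e-9, rel=1e-3)

    def test_zero_callable_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate(5, 0)

    def test_cohort_rate_matches_generative_truth(self, full_cohort):
        counts = full_cohort.dnms.groupby("trio_id").size()
        n = counts.reindex([t.trio_id for t in full_cohort.trios], fill_value=0).sum()
        size = sum(
            2 * full_cohort.callable_sites[t.trio_id]["AUTOSOME"]
            for t in full_cohort.trios
        )
        rate = mutation_rate(int(n), size)
        # 8000+ Poisson counts: ~1.1% sampling SE on the cohort rate
        assert rate == pytest.approx(full_cohort.config.target_rate, rel=0.04)


class TestBootstrap:
    def test_degenerate_identical_trios(self):
        est = bootstrap_rate([21] * 10, [4.3e9] * 10, n_boot=200, seed=1)
        assert est.ci_low == est.ci_high == pytest.approx(est.rate)

    def test_deterministic_given_seed(self):
        a = bootstrap_rate([10, 20, 30], [1e9, 2e9, 3e9], n_boot=500, seed=42)
        b = bootstrap_rate([10, 20, 30], [1e9, 2e9, 3e9], n_boot=500, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_brackets_point(self, full_cohort):
        counts = full_cohort.dnms.groupby("trio_id").size()
        n = counts.reindex([t.trio_id for t in full_cohort.trios], fill_value=0).to_numpy(float)
        sizes = np.array(
            [2 * full_cohort.callable_sites[t.trio_id]["AUTOSOME"] for t in full_cohort.trios],
            float,
        )
        est = bootstrap_rate(n, sizes, n_boot=2000, seed=9)
        assert est.ci_low <= est.rate <= est.ci_high
        assert est.ci_low <= full_cohort.config.target_rate <= est.ci_high

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_rate([1, 2], [1e9, 1e9], n_boot=200, seed=None)

    def test_ci_width_shrinks_with_cohort_size(self):
        rng = np.random.default_rng(3)
        widths = []
        for n in (50, 450):
            counts = rng.poisson(21, n).astype(float)
            est = bootstrap_rate(counts, np.full(n, 4.3e9), n_boot=1500, seed=5)
            widths.append(est.ci_high - est.ci_low)
        # 9x the trios -> about 3x narrower
        assert widths[1] < widths[0] / 2


class TestConservation:
    def test_regional_rates_recombine_to_genome_rate(self, small_cohort):
        """Region-partitioned counts weighted by callable sizes pool back
        to the genome-wide rate."""
        d = small_cohort.dnms
        sizes = {
            lbl: sum(2 * small_cohort.callable_sites[t.trio_id][lbl]
                     for t in small_cohort.trios)
            for lbl in ("HMR_CGI",)
        }
        auto_size = sum(2 * small_cohort.callable_sites[t.trio_id]["AUTOSOME"]
                        for t in small_cohort.trios)
        n_hmr = int(d.in_hmr_cgi.sum())
        n_rest = len(d) - n_hmr
        rest_size = auto_size - sizes["HMR_CGI"]
        pooled = (
            mutation_rate(n_hmr, sizes["HMR_CGI"]) * sizes["HMR_CGI"]
            + mutation_rate(n_rest, rest_size) * rest_size
        ) / auto_size
        assert pooled == pytest.approx(mutation_rate(len(d), auto_size), rel=1e-12)


class TestCompositionCorrection:
    def test_identity_when_composition_matches(self):
        """HMR composition equal to the genome average leaves per-class
        folds equal to the uncorrected fold."""
        comp = CompositionTable({
            "AUTOSOME": {"AT": 0.6, "CG": 0.38, "CpG": 0.02},
            "HMR_CGI": {"AT": 0.6, "CG": 0.38, "CpG": 0.02},
        })
        counts = {"C>T": np.array([30, 28, 35]), "T>C": np.array([31, 29, 30])}
        hmr_counts = {k: v * 2 for k, v in counts.items()}
        sizes = np.array([1e9, 1e9, 1e9])
        hmr_sizes = sizes / 100
        auto = composition_corrected_rates(counts, sizes, comp, "AUTOSOME",
                                           n_boot=100, seed=1)
        hmr = composition_corrected_rates(hmr_counts, hmr_sizes, comp, "HMR_CGI",
                                          n_boot=100, seed=1)
        for mclass in counts:
            corrected_fold = hmr[mclass].rate / auto[mclass].rate
            uncorrected = (hmr_counts[mclass].sum() / hmr_sizes.sum()) / (
                counts[mclass].sum() / sizes.sum()
            )
            assert corrected_fold == pytest.approx(uncorrected, rel=1e-12)

    def test_uniform_enrichment_recovered_per_class(self, full_cohort):
        """A uniform HMR fold shows up in each class's corrected rate."""
        d = full_cohort.dnms
        comp = CompositionTable({
            "AUTOSOME": {"AT": 0.6, "CG": 0.37, "CpG": 0.03},
            "HMR_CGI": {"AT": 0.6, "CG": 0.37, "CpG": 0.03},
        })
        trios = full_cohort.trios
        sizes = np.array([2 * full_cohort.callable_sites[t.trio_id]["AUTOSOME"]
                          for t in trios], float)
        hmr_sizes = np.array([2 * full_cohort.callable_sites[t.trio_id]["HMR_CGI"]
                              for t in trios], float)
        folds = []
        for mclass in ("C>T", "T>C", "CpG>TpG"):
            sub = d[d.mutation_class == mclass]
            per = sub.groupby("trio_id").size()
            per_hmr = sub[sub.in_hmr_cgi].groupby("trio_id").size()
            counts = {mclass: np.array([per.get(t.trio_id, 0) for t in trios], float)}
            h_counts = {mclass: np.array([per_hmr.get(t.trio_id, 0) for t in trios], float)}
            a = composition_corrected_rates(counts, sizes, comp, "AUTOSOME",
                                            n_boot=100, seed=2)[mclass]
            h = composition_corrected_rates(h_counts, hmr_sizes, comp, "HMR_CGI",
                                            n_boot=100, seed=2)[mclass]
            folds.append(h.rate / a.rate)
        # ~100-500 HMR mutations per class: generous sampling tolerance
        assert np.allclose(folds, full_cohort.config.hmr_fold, rtol=0.35)

    def test_zero_opportunity_with_dnms_rejected(self):
        comp = CompositionTable({"R": {"AT": 1.0, "CG": 0.0, "CpG": 0.0}})
        with pytest.raises(ValueError, match="opportunity"):
            composition_corrected_rates({"C>T": np.array([1, 2])},
                                        np.array([1e6, 1e6]), comp, "R",
                                        n_boot=100, seed=1)

    def test_zero_opportunity_zero_dnms_absent(self):
        comp = CompositionTable({"R": {"AT": 1.0, "CG": 0.0, "CpG": 0.0}})
        out = composition_corrected_rates({"CpG>TpG": np.array([0, 0])},
                                          np.array([1e6, 1e6]), comp, "R",
                                          n_boot=100, seed=1)
        assert out == {}


class TestClosedForms:
    def test_x_autosome_ratio_at_study_alpha(self):
        assert expected_x_autosome_ratio(3.01) == pytest.approx(0.83, abs=0.005)

    def test_x_autosome_ratio_limits(self):
        assert expected_x_autosome_ratio(1.0) == pytest.approx(1.0)
        assert expected_x_autosome_ratio(1e9) == pytest.approx(2.0 / 3.0, rel=1e-6)

    def test_x_autosome_ratio_monotone_decreasing(self):
        alphas = np.linspace(0.1, 20, 50)
        vals = [expected_x_autosome_ratio(a) for a in alphas]
        assert np.all(np.diff(vals) < 0)

    def test_phased_sex_ratio_study_values(self):
        frac, alpha = phased_sex_ratio(1941, 645)  # 75.05% of 2586
        assert frac == pytest.approx(0.7505, abs=2e-4)
        assert alpha == pytest.approx(3.01, abs=0.01)

    @pytest.mark.parametrize("p, m, expected", [((1), 1, (0.5, 1.0)), (3, 1, (0.75, 3.0))])
    def test_phased_sex_ratio_trivial(self, p, m, expected):
        assert phased_sex_ratio(p, m) == pytest.approx(expected)

    def test_phased_sex_ratio_no_maternal(self):
        frac, alpha = phased_sex_ratio(5, 0)
        assert frac == 1.0 and alpha == float("inf")

    def test_par_rates_study_values(self):
        male, female, avg = par_recombination_rates(6.8)
        assert male == pytest.approx(14.7, abs=0.01)
        assert avg == pytest.approx(7.85, abs=0.005)

    def test_par_rates_trivial(self):
        assert par_recombination_rates(100)[::2] == pytest.approx((1.0, 1.0))
        male, _, avg = par_recombination_rates(6.8, obligate_map_length_cM=0)
        assert (male, avg) == (0.0, 0.5)


class TestRecombinationMutagenesis:
    def test_study_accounting(self):
        r = recombination_mutagenesis(117, 2.34, 389, 21.31)
        assert r.expected_count == pytest.approx(50.0, abs=0.01)
        assert r.excess_total == pytest.approx(67.0, abs=0.01)
        assert r.excess_per_trio == pytest.approx(0.172, abs=5e-4)
        assert r.fraction_of_all_mutations == pytest.approx(0.008, abs=5e-4)
        assert r.enrichment_p < 1e-12

    def test_fold_one_no_excess(self):
        r = recombination_mutagenesis(10, 1.0, 10, 2.0)
        assert r.excess_total == 0 and r.fraction_of_all_mutations == 0

    def test_hand_arithmetic(self):
        r = recombination_mutagenesis(10, 2, 10, 1)
        assert (r.expected_count, r.excess_total, r.excess_per_trio,
                r.fraction_of_all_mutations) == (5.0, 5.0, 0.5, 0.5)

    def test_depletion_warns(self):
        with pytest.warns(UserWarning, match="depletion"):
            recombination_mutagenesis(10, 0.5, 10, 1)
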