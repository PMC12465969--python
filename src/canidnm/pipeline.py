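"""End-to-end orchestration on synthetic (or user-supplied) cohorts.

``run_pipeline`` executes the stages in dependency order -- simulate,
call, rates, age models, spectrum/sharing, crossovers, branch-ratio
dating -- and emits a single JSON report plus TSV tables, with every
seed and threshold echoed for provenance.  ``cohort_summary`` produces
the headline cohort statistics.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from canidnm import age_models, rates, sharing, spectrum
from canidnm.calling import (
    DEFAULT_THRESHOLDS,
    apply_dnm_filters,
    compute_callable_profile,
    exclude_low_depth_trios,
)
from canidnm.crossovers import detect_crossovers, dnm_crossover_proximity
from canidnm.phylo import branch_ratios, estimate_loss_time
from canidnm.simulate import (
    DEFAULT_TIME_TREE,
    SimulationConfig,
    simulate_cohort,
    simulate_marker_track,
    simulate_ratioed_phylogeny,
    simulate_site_evidence,
)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's printed values."""

    seed: int = 0
    out_dir: str = "canidnm_out"
    simulation: SimulationConfig | None = None
    stages: tuple = ("call", "rates", "agefit", "spectrum", "sharing", "crossovers", "prdm9")
    n_boot_rates: int = 10_000
    n_boot_sharing: int = 1000
    n_resamples_prdm9: int = 1000
    proximity_window_bp: float = 10_000
    crossovers_per_meiosis: float = 18.3
    n_markers_crossovers: int = 50_000
    time_tree: str = DEFAULT_TIME_TREE
    prdm9_r0: float = 1.0
    prdm9_r1: float = 2.5
    prdm9_loss_mya: float = 37.3
    prdm9_noise_sd: float = 0.01

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def cohort_summary(dnms: pd.DataFrame, trios, callable_profiles) -> dict:
    """Headline cohort statistics.

    Mean DNMs per trio with a normal-approximation 95% CI on the mean,
    the phased fraction, the paternal fraction of phased DNMs and the
    implied male-to-female ratio, and the mean callable genome
    fraction.
    """
    if not len(trios):
        raise ValueError("empty cohort")
    counts = (
        dnms.groupby("trio_id").size().reindex([t.trio_id for t in trios], fill_value=0)
    )
    mean = float(counts.mean())
    if len(counts) > 1 and counts.std(ddof=1) > 0:
        half = stats.norm.ppf(0.975) * counts.std(ddof=1) / np.sqrt(len(counts))
        ci = (mean - half, mean + half)
        degenerate = False
    else:
        ci = (mean, mean)
        degenerate = True
    phased = dnms[dnms["phase"] != "unphased"]
    n_pat = int((phased["phase"] == "paternal").sum())
    n_mat = int((phased["phase"] == "maternal").sum())
    if n_pat + n_mat:
        pat_frac, alpha = rates.phased_sex_ratio(n_pat, n_mat)
    else:
        pat_frac, alpha = float("nan"), float("nan")
    call_frac = (
        float(np.mean([p.callable_fraction for p in callable_profiles]))
        if callable_profiles
        else float("nan")
    )
    return {
        "n_trios": len(trios),
        "n_dnms": int(len(dnms)),
        "mean_dnms_per_trio": mean,
        "mean_dnms_ci": ci,
        "ci_degenerate": degenerate,
        "phased_fraction": len(phased) / len(dnms) if len(dnms) else float("nan"),
        "paternal_fraction": pat_frac,
        "alpha": alpha,
        "mean_callable_fraction": call_frac,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the toggled stages end-to-end and write the report bundle.

    Stage outputs feed forward; disabling a stage removes its section
    from the report, and stages requiring a disabled predecessor raise.
    Identical seeds reproduce identical numeric fields.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
    report: dict = {"seeds": {"master": config.seed, "simulation": sim_cfg.seed}}
    timings = {}

    t0 = time.time()
    cohort = simulate_cohort(sim_cfg)
    trios = exclude_low_depth_trios(cohort.trios)
    timings["simulate"] = time.time() - t0

    dnms = cohort.dnms
    profiles = [
        compute_callable_profile(
            cohort.callable_sites[t.trio_id], t, cohort.region_map.genome_size()
        )
        for t in trios
    ]
    prof_by_trio = {p.trio_id: p for p in profiles}

    if "call" in config.stages:
        t0 = time.time()
        evidence = simulate_site_evidence(cohort, seed=config.seed + 1, noise=False)
        trio_index = cohort.trio_index
        verdicts = [
            apply_dnm_filters(site, trio_index[tid], cohort.region_map)
            for tid, site, _ in evidence
        ]
        n_pass = sum(v.passed for v in verdicts)
        report["call"] = {
            "n_candidates": len(verdicts),
            "n_pass": n_pass,
            "thresholds": asdict(DEFAULT_THRESHOLDS),
        }
        timings["call"] = time.time() - t0

    report["cohort"] = cohort_summary(dnms, trios, profiles)

    if "rates" in config.stages:
        t0 = time.time()
        counts = dnms.groupby("trio_id").size()
        per_trio_counts = np.array([counts.get(t.trio_id, 0) for t in trios], float)
        sizes = np.array(
            [prof_by_trio[t.trio_id].callable_size["AUTOSOME"] for t in trios], float
        )
        est = rates.bootstrap_rate(
            per_trio_counts, sizes, n_boot=config.n_boot_rates, seed=config.seed + 2
        )
        hmr_counts = dnms[dnms["in_hmr_cgi"]].groupby("trio_id").size()
        per_trio_hmr = np.array([hmr_counts.get(t.trio_id, 0) for t in trios], float)
        hmr_sizes = np.array(
            [prof_by_trio[t.trio_id].callable_size["HMR_CGI"] for t in trios], float
        )
        hmr_est = rates.bootstrap_rate(
            per_trio_hmr, hmr_sizes, n_boot=config.n_boot_rates,
            seed=config.seed + 3, region="HMR_CGI",
        )
        fold = hmr_est.rate / est.rate
        recomb = rates.recombination_mutagenesis(
            observed_in_hmr=float(per_trio_hmr.sum()),
            corrected_fold=fold if fold > 0 else 1.0,
            n_trios=len(trios),
            mean_dnm_per_trio=float(per_trio_counts.mean()),
        )
        report["rates"] = {
            "genome": vars(est),
            "hmr_cgi": vars(hmr_est),
            "hmr_fold": fold,
            "recombination_mutagenesis": vars(recomb),
        }
        timings["rates"] = time.time() - t0

    if "agefit" in config.stages:
        t0 = time.time()
        fits = {}
        for sex, col_age in (("paternal", "paternal_age_years"), ("maternal", "maternal_age_years")):
            phased = dnms[dnms["phase"] == sex].groupby("trio_id").size()
            cts = np.array([phased.get(t.trio_id, 0) for t in trios], float)
            ages = np.array([getattr(t, col_age) for t in trios])
            expo = np.array(
                [prof_by_trio[t.trio_id].callable_size["AUTOSOME"] / 2 for t in trios],
                float,
            )
            fit = age_models.fit_phased_age_model(cts, ages, expo, sex=sex, method="ML")
            fits[sex] = fit
            report.setdefault("agefit", {})[sex] = {
                "b0": fit.b0,
                "b1": fit.b1,
                "b0_interval": fit.b0_interval,
                "b1_interval": fit.b1_interval,
                "mcfadden_r2": age_models.mcfadden_r2(fit),
                "n_trios": fit.n_trios,
            }
        yr, slope_sum = age_models.yearly_rate(
            fits["paternal"],
            fits["maternal"],
            float(np.mean([t.paternal_age_years for t in trios])),
            float(np.mean([t.maternal_age_years for t in trios])),
        )
        report["agefit"]["yearly_rate"] = yr
        report["agefit"]["yearly_rate_slope_sum"] = slope_sum
        timings["agefit"] = time.time() - t0

    if "spectrum" in config.stages:
        t0 = time.time()
        table = spectrum.spectrum_table(dnms["mutation_class"], cohort="synthetic")
        hyper = spectrum.flag_hypermutators(
            [t.trio_id for t in trios],
            [int(dnms[dnms.trio_id == t.trio_id].shape[0]) for t in trios],
        )
        report["spectrum"] = {
            "fractions": table.fractions,
            "total": table.total,
            "n_hypermutators_flagged": int(hyper["flagged"].sum()),
        }
        timings["spectrum"] = time.time() - t0

    if "sharing" in config.stages:
        t0 = time.time()
        pedigree = {t.offspring_id: (t.sire_id, t.dam_id) for t in cohort.trios}
        summary = sharing.find_shared_mutations(dnms, pedigree)
        if len(summary.pair_table):
            frac, ci = sharing.shared_fraction_bootstrap(
                summary, n_boot=config.n_boot_sharing, seed=config.seed + 4
            )
        else:
            frac, ci = 0.0, (0.0, 0.0)
        report["sharing"] = {
            "n_groups": int(len(summary.groups)),
            "fraction": frac,
            "ci": ci,
        }
        timings["sharing"] = time.time() - t0

    if "crossovers" in config.stages:
        t0 = time.time()
        rng = np.random.default_rng(config.seed + 5)
        genome = cohort.region_map.span("AUTOSOME")
        bps_by_trio, dnm_pos_by_trio = {}, {}
        offset = {"A1": 0, "A2": cohort.region_map.contigs["A1"]}
        for k, t in enumerate(trios):
            n_co = rng.poisson(config.crossovers_per_meiosis)
            pos, orig, _ = simulate_marker_track(
                genome, n_markers=config.n_markers_crossovers, n_crossovers=n_co,
                seed=int(rng.integers(2**31)),
            )
            bps_by_trio[t.trio_id] = detect_crossovers(pos, orig, min_block=500)
            sub = dnms[dnms.trio_id == t.trio_id]
            dnm_pos_by_trio[t.trio_id] = [
                offset[c] + p for c, p in zip(sub.contig, sub.pos)
            ]
        obs, exp, p = dnm_crossover_proximity(
            dnm_pos_by_trio, bps_by_trio, genome_size=genome,
            window_bp=config.proximity_window_bp,
        )
        report["crossovers"] = {
            "n_crossovers": int(sum(len(b) for b in bps_by_trio.values())),
            "observed_near": obs,
            "expected_near": exp,
            "p": p,
        }
        timings["crossovers"] = time.time() - t0

    if "prdm9" in config.stages:
        t0 = time.time()
        auto, hmr = simulate_ratioed_phylogeny(
            config.time_tree,
            r0=config.prdm9_r0,
            r1=config.prdm9_r1,
            loss_time=config.prdm9_loss_mya,
            noise_sd=config.prdm9_noise_sd,
            seed=config.seed + 6,
        )
        ratioed = branch_ratios(hmr, auto)
        roles = {
            "full": [("dog", "african_wild_dog")],
            "pre": [("dog", "african_wild_dog", "fox", "bear")],
            "transition": ("dog", "african_wild_dog", "fox"),
        }
        est = estimate_loss_time(
            ratioed,
            config.time_tree,
            roles,
            n_resamples=config.n_resamples_prdm9,
            resample_noise_sd=config.prdm9_noise_sd,
            seed=config.seed + 7,
        )
        report["prdm9"] = {
            "loss_mya": est.point_mya,
            "ci": (est.ci_low, est.ci_high),
            "r0": est.r0,
            "r1": est.r1,
            "r_obs": est.r_obs,
        }
        timings["prdm9"] = time.time() - t0

    report["timings_s"] = timings
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonify)
    dnms.to_csv(os.path.join(config.out_dir, "dnms.tsv"), sep="\t", index=False)
    return report


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return str(obj)
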