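"""Mutation-rate estimation: pooled and bootstrap rates, composition
correction, X/autosome and PAR expectations, and recombination
mutagenesis accounting.

The per-generation rate is the pooled ratio of DNM counts to callable
size (the callable-site count already scaled x2 per diploid region, x1
on the male X-unique region).  Confidence intervals come from
trio-level bootstrap resampling with percentile quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RateEstimate:
    """A mutation rate (per bp per generation) with a bootstrap CI."""

    rate: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None
    region: str = "AUTOSOME"
    mutation_class: str | None = None

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")


@dataclass
class CompositionTable:
    """Per-region fractions of mutational-opportunity base classes.

    For each region: fraction of A/T sites, of C/G sites outside CpG
    dinucleotides, and of CpG-dinucleotide sites.  The three fractions
    sum to one per region.
    """

    fractions: dict  # region -> {"AT": f, "CG": f, "CpG": f}

    def __post_init__(self):
        for region, f in self.fractions.items():
            total = f["AT"] + f["CG"] + f["CpG"]
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{region}: composition fractions sum to {total}")

    def opportunity_fraction(self, region: str, mutation_class: str) -> float:
        f = self.fractions[region]
        if mutation_class == "CpG>TpG":
            return f["CpG"]
        if mutation_class.startswith("C>"):
            return f["CG"]
        if mutation_class.startswith("T>"):
            return f["AT"]
        raise ValueError(f"unknown mutation class {mutation_class!r}")


def mutation_rate(n_dnm: int, callable_size_sum: float) -> float:
    """Pooled mutation rate: DNM count over summed callable size."""
    if callable_size_sum <= 0:
        raise ValueError("callable size must be positive")
    if n_dnm < 0:
        raise ValueError("DNM count must be nonnegative")
    return n_dnm / callable_size_sum


def bootstrap_rate(
    dnm_counts,
    callable_sizes,
    n_boot: int = 10_000,
    seed: int | None = None,
    region: str = "AUTOSOME",
    mutation_class: str | None = None,
) -> RateEstimate:
    """Trio-level bootstrap of the pooled rate with a percentile 95% CI.

    ``dnm_counts[i]`` and ``callable_sizes[i]`` belong to trio i; each
    round resamples trios with replacement and recomputes
    sum(counts)/sum(sizes).
    """
    counts = np.asarray(dnm_counts, dtype=float)
    sizes = np.asarray(callable_sizes, dtype=float)
    if counts.shape != sizes.shape or counts.ndim != 1:
        raise ValueError("counts and sizes must be 1-d arrays of equal length")
    if len(counts) < 2:
        raise ValueError("bootstrap needs at least 2 trios")
    if seed is None:
        raise ValueError("seed is mandatory for reproducible bootstrap")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile CIs", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(counts)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = counts[idx].sum(axis=1) / sizes[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RateEstimate(
        rate=mutation_rate(counts.sum(), sizes.sum()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        region=region,
        mutation_class=mutation_class,
    )


def composition_corrected_rates(
    class_counts: dict,
    callable_sizes,
    composition: CompositionTable,
    region: str,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Per-mutation-class rates with the denominator scaled by opportunity.

    The callable size of a region is multiplied by the fraction of bases
    offering each class's mutational opportunity (C/G sites for C>*
    classes, A/T sites for T>* classes, CpG-dinucleotide sites for
    CpG>TpG) before the rate and its bootstrap CI are computed.

    ``class_counts`` maps class -> per-trio count array; all arrays must
    align with ``callable_sizes``.  A class whose opportunity fraction
    is zero is rejected if it has DNMs, and omitted otherwise.
    """
    sizes = np.asarray(callable_sizes, dtype=float)
    out = {}
    for mclass, counts in class_counts.items():
        counts = np.asarray(counts, dtype=float)
        frac = composition.opportunity_fraction(region, mclass)
        if frac == 0:
            if counts.sum() > 0:
                raise ValueError(
                    f"{region}/{mclass}: DNMs observed with zero opportunity"
                )
            continue  # class undefined here, reported as absent
        out[mclass] = bootstrap_rate(
            counts, sizes * frac, n_boot=n_boot, seed=seed,
            region=region, mutation_class=mclass,
        )
    return out


def expected_x_autosome_ratio(alpha: float) -> float:
    """Expected X/autosome mutation-rate ratio, 2(2+a)/(3(1+a)).

    Follows from males carrying one X to the females' two while
    contributing ``alpha`` times the female mutation rate per
    generation.
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    return 2.0 * (2.0 + alpha) / (3.0 * (1.0 + alpha))


def phased_sex_ratio(n_paternal: int, n_maternal: int):
    """Paternal fraction and male-to-female ratio from phased counts.

    Returns ``(paternal_fraction, alpha)``; with no maternal mutations,
    alpha is reported as ``inf``.
    """
    if n_paternal < 0 or n_maternal < 0:
        raise ValueError("phased counts must be nonnegative")
    total = n_paternal + n_maternal
    if total == 0:
        raise ValueError("no phased mutations")
    fraction = n_paternal / total
    alpha = n_paternal / n_maternal if n_maternal > 0 else float("inf")
    return fraction, alpha


def par_recombination_rates(
    par_length_mb: float,
    obligate_map_length_cM: float = 100.0,
    female_rate_cM_per_Mb: float = 1.0,
):
    """Male, female, and sex-averaged recombination rates in the PAR.

    One obligate male crossover in the PAR per meiosis spreads a full
    ``obligate_map_length_cM`` genetic map over the PAR's physical
    length, so the male rate is map length / physical length.
    """
    if not par_length_mb > 0:
        raise ValueError("PAR length must be positive")
    male = obligate_map_length_cM / par_length_mb
    sex_averaged = (male + female_rate_cM_per_Mb) / 2.0
    return male, female_rate_cM_per_Mb, sex_averaged


@dataclass
class RecombinationMutagenesis:
    expected_count: float
    excess_total: float
    excess_per_trio: float
    fraction_of_all_mutations: float
    enrichment_p: float


def recombination_mutagenesis(
    observed_in_hmr: float,
    corrected_fold: float,
    n_trios: int,
    mean_dnm_per_trio: float,
) -> RecombinationMutagenesis:
    """Mutational excess in hypomethylated CGIs ascribed to recombination.

    Under the genome-wide rate one expects observed/fold mutations in
    the region; the excess over that expectation, per trio and as a
    fraction of all mutations, quantifies the mutagenic effect of
    recombination.  A one-sided Poisson tail p-value tests the
    enrichment of the observed count over the expectation.
    """
    if not corrected_fold > 0:
        raise ValueError("fold must be positive")
    if not n_trios > 0:
        raise ValueError("n_trios must be positive")
    if corrected_fold < 1:
        warnings.warn("fold < 1 implies depletion; formulas still apply", stacklevel=2)
    expected = observed_in_hmr / corrected_fold
    excess = observed_in_hmr - expected
    per_trio = excess / n_trios
    fraction = per_trio / mean_dnm_per_trio
    p = float(stats.poisson.sf(int(np.ceil(observed_in_hmr)) - 1, expected))
    return RecombinationMutagenesis(expected, excess, per_trio, fraction, p)
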