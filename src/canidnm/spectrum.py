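"""Mutational-spectrum tables, cross-species class tests, paternal-age
spectrum trends, and hypermutation flagging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from canidnm.records import MUTATION_CLASSES

#: Bonferroni family size for cross-species class tests (7 base classes
#: plus the CGI-overlap class tested alongside them).
N_CLASS_TESTS = 8
BONFERRONI_ALPHA = 0.05 / N_CLASS_TESTS  # 0.00625


@dataclass
class SpectrumTable:
    """Counts and fractions of DNMs per mutation class for one cohort."""

    counts: dict
    cohort: str = ""
    region: str | None = None

    def __post_init__(self):
        for mclass, n in self.counts.items():
            if mclass not in MUTATION_CLASSES:
                raise ValueError(f"unknown class {mclass!r}")
            if n < 0 or int(n) != n:
                raise ValueError(f"count for {mclass} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def fractions(self) -> dict:
        t = self.total
        return {c: self.counts.get(c, 0) / t for c in MUTATION_CLASSES} if t else {}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mutation_class": list(MUTATION_CLASSES),
                "count": [self.counts.get(c, 0) for c in MUTATION_CLASSES],
                "fraction": [self.fractions.get(c, 0.0) for c in MUTATION_CLASSES],
            }
        )


def spectrum_table(mutation_classes, cohort: str = "", region: str | None = None) -> SpectrumTable:
    """Tally a sequence of mutation-class labels into a SpectrumTable."""
    counts = {c: 0 for c in MUTATION_CLASSES}
    for mclass in mutation_classes:
        if mclass not in counts:
            raise ValueError(f"unknown class {mclass!r}")
        counts[mclass] += 1
    return SpectrumTable(counts, cohort=cohort, region=region)


def cross_species_class_test(counts_a: dict, counts_b: dict, mutation_class: str):
    """Fisher's exact test of one class's share between two cohorts.

    Builds the 2x2 table (in-class vs not, cohort A vs B) and applies a
    two-sided Fisher exact test; significance is declared at the
    Bonferroni-corrected threshold p < 0.05/8.  Returns
    (odds_ratio, p, significant); with the class absent from both
    cohorts the odds ratio is NaN and p = 1.
    """
    total_a, total_b = sum(counts_a.values()), sum(counts_b.values())
    if total_a == 0 or total_b == 0:
        raise ValueError("both cohorts need at least one mutation")
    in_a = counts_a.get(mutation_class, 0)
    in_b = counts_b.get(mutation_class, 0)
    if in_a == 0 and in_b == 0:
        return float("nan"), 1.0, False
    table = [[in_a, total_a - in_a], [in_b, total_b - in_b]]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p), bool(p < BONFERRONI_ALPHA)


def paternal_age_class_trend(paternal_ages, mutation_classes, mutation_class: str):
    """Weighted trend of a class's fraction with paternal age.

    DNMs are binned by (integer-rounded) paternal age; per-bin class
    fractions are regressed on age by weighted least squares with the
    bin totals as weights.  Returns (slope per year, two-sided p).
    Bins with zero total are dropped.
    """
    import statsmodels.api as sm

    ages = np.round(np.asarray(paternal_ages, dtype=float)).astype(int)
    is_class = np.asarray([c == mutation_class for c in mutation_classes])
    if len(ages) != len(is_class):
        raise ValueError("ages and classes must align")
    bins = np.unique(ages)
    fractions, totals, xs = [], [], []
    for b in bins:
        mask = ages == b
        n = int(mask.sum())
        if n == 0:
            continue
        fractions.append(is_class[mask].mean())
        totals.append(n)
        xs.append(float(b))
    if len(xs) < 2:
        raise ValueError("need at least 2 age bins with observations")
    X = sm.add_constant(np.asarray(xs))
    model = sm.WLS(np.asarray(fractions), X, weights=np.asarray(totals, dtype=float))
    res = model.fit()
    slope = float(res.params[1])
    p = float(res.pvalues[1]) if len(xs) > 2 else float("nan")
    return slope, p


def flag_hypermutators(trio_ids, dnm_counts, alpha: float = 0.05):
    """Flag trios with significantly excessive DNM counts.

    For each trio, the fold excess is its count over the cohort median
    (computed excluding the trio itself); the flag is raised when the
    upper-tail Poisson probability of the count at the cohort mean
    (excluding self), Bonferroni-adjusted across trios, is below
    ``alpha``.  Returns a DataFrame (trio_id, count, fold, p_adjusted,
    flagged).
    """
    counts = np.asarray(dnm_counts, dtype=float)
    n = len(counts)
    if n < 10:
        raise ValueError("need at least 10 trios")
    rows = []
    for i, trio_id in enumerate(trio_ids):
        others = np.delete(counts, i)
        med = np.median(others)
        if med == 0:
            raise ValueError("cohort median of zero")
        fold = counts[i] / med
        p = stats.poisson.sf(counts[i] - 1, others.mean())
        p_adj = min(p * n, 1.0)
        rows.append((trio_id, int(counts[i]), float(fold), float(p_adj), bool(p_adj < alpha)))
    return pd.DataFrame(rows, columns=["trio_id", "count", "fold", "p_adjusted", "flagged"])


def phase_balance_test(n_maternal: int, n_paternal: int, expected_paternal_fraction: float = 0.5) -> float:
    """Two-sided exact binomial test of the paternal share of phased DNMs.

    Tests the observed paternal count against the supplied expectation
    (0.5 under equal-sex accrual of early developmental mutations).
    """
    total = n_maternal + n_paternal
    if total == 0:
        raise ValueError("no phased mutations to test")
    res = stats.binomtest(n_paternal, total, expected_paternal_fraction, alternative="two-sided")
    return float(res.pvalue)
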