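"""Phased parental-age Poisson regression on the identity scale.

The phased DNM count of trio i is modelled as

    count_i ~ Poisson((b0 + b1 * age_i) * E_i)

where ``age_i`` is the age of the relevant parent at conception (years)
and ``E_i`` the exposure, by default the trio's haploid autosomal
callable size attributable to that parent.  The identity link keeps b1
an additive per-year effect in mutations/bp/year, the scale on which
parental-age effects are conventionally reported.  Nonnegativity of the
fitted mean over the observed age range is enforced by a barrier in the
ML objective; the Bayesian variant samples under half-normal priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class AgeModelFit:
    """Fitted identity-link Poisson age model for one parental sex."""

    sex: str  # 'paternal' | 'maternal'
    b0: float  # mutations/bp at age 0 (regression intercept)
    b1: float  # mutations/bp/year
    b0_interval: tuple
    b1_interval: tuple
    loglik: float
    loglik_null: float
    n_trios: int
    method: str = "ML"
    exposure_convention: str = "haploid_callable"
    seed: int | None = None
    boundary: bool = False  # degenerate all-zero-count fit
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def mcfadden_r2(self) -> float:
        return mcfadden_r2(self)


def poisson_loglik(b0: float, b1: float, counts, ages, exposures) -> float:
    """Exact Poisson log-likelihood of the identity-link model."""
    mu = (b0 + b1 * np.asarray(ages)) * np.asarray(exposures)
    if np.any(mu < 0) or (np.any(mu == 0) and np.any(np.asarray(counts)[mu == 0] > 0)):
        return -np.inf
    return float(stats.poisson.logpmf(counts, np.clip(mu, 1e-300, None)).sum())


def _null_loglik(counts, exposures) -> float:
    counts = np.asarray(counts, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    m0 = counts.sum() / exposures.sum()
    return float(stats.poisson.logpmf(counts, np.clip(m0 * exposures, 1e-300, None)).sum())


def _ml_fit(counts, ages, exposures):
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    exposures = np.asarray(exposures, dtype=float)

    # moment start: weighted LS of count/exposure on age
    rate = counts / exposures
    A = np.column_stack([np.ones_like(ages), ages])
    w = exposures
    beta0, _, _, _ = np.linalg.lstsq(A * w[:, None] ** 0.5, rate * w**0.5, rcond=None)
    start = np.array([max(beta0[0], 1e-12), beta0[1]])

    def nll(params):
        return -poisson_loglik(params[0], params[1], counts, ages, exposures)

    best = None
    for s in (start, np.array([counts.sum() / exposures.sum(), 0.0])):
        res = optimize.minimize(nll, s, method="Nelder-Mead",
                                options={"xatol": 1e-14, "fatol": 1e-12, "maxiter": 20_000})
        if best is None or res.fun < best.fun:
            best = res
    b0, b1 = best.x
    # observed information of the identity-link Poisson model
    r = b0 + b1 * ages
    with np.errstate(divide="ignore", invalid="ignore"):
        wgt = np.where(r > 0, counts / np.maximum(r, 1e-300) ** 2, 0.0)
    info = np.array([[wgt.sum(), (wgt * ages).sum()],
                     [(wgt * ages).sum(), (wgt * ages**2).sum()]])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return b0, b1, -best.fun, cov


def _bayes_fit(counts, ages, exposures, seed, n_walkers=16, n_steps=2000, burn=500):
    import emcee

    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    # half-normal priors scaled 10x a crude moment estimate
    crude = max(counts.sum() / exposures.sum(), 1e-12)
    scale0, scale1 = 10 * crude, 10 * crude / max(ages.mean(), 1e-9)

    def logpost(params):
        b0, b1 = params
        if b0 < 0 or b1 < 0:
            return -np.inf
        lp = -0.5 * (b0 / scale0) ** 2 - 0.5 * (b1 / scale1) ** 2
        return lp + poisson_loglik(b0, b1, counts, ages, exposures)

    rng = np.random.default_rng(seed)
    p0 = np.abs(rng.normal([crude, crude / ages.mean()],
                           [crude / 4, crude / ages.mean() / 4],
                           size=(n_walkers, 2)))
    sampler = emcee.EnsembleSampler(n_walkers, 2, logpost)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=burn)  # (steps, walkers, 2)
    rhat = _gelman_rubin(chain)
    if np.any(rhat > 1.05):
        import warnings

        warnings.warn(f"MCMC convergence diagnostic R-hat {rhat} > 1.05", stacklevel=2)
    flat = chain.reshape(-1, 2)
    return flat


def _gelman_rubin(chain) -> np.ndarray:
    """Split-free R-hat across walkers for each parameter."""
    n, m, _ = chain.shape
    means = chain.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    W = chain.var(axis=0, ddof=1).mean(axis=0)
    var_hat = (n - 1) / n * W + B / n
    return np.sqrt(var_hat / W)


def hdi(samples, prob: float = 0.95) -> tuple:
    """Smallest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples))
    n = len(x)
    k = int(np.floor(prob * n))
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def fit_phased_age_model(
    counts,
    ages,
    exposures,
    sex: str = "paternal",
    method: str = "ML",
    seed: int | None = None,
) -> AgeModelFit:
    """Fit the identity-link Poisson parental-age model.

    Parameters
    ----------
    counts, ages, exposures : array-like
        Per-trio phased DNM counts, parental ages at conception (years),
        and exposures (haploid callable bp by default).
    method : {'ML', 'Bayes'}
        Constrained maximum likelihood with Wald intervals, or an
        ensemble MCMC sampler under half-normal priors with HDIs.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if not (len(counts) == len(ages) == len(exposures)):
        raise ValueError("counts, ages and exposures must align")
    if len(counts) < 2:
        raise ValueError("need at least 2 trios")
    if np.var(ages) == 0:
        raise ValueError("zero age variance: slope unidentifiable")
    ll_null = _null_loglik(counts, exposures)

    if counts.sum() == 0:
        return AgeModelFit(sex, 0.0, 0.0, (0.0, 0.0), (0.0, 0.0),
                           loglik=0.0, loglik_null=0.0, n_trios=len(counts),
                           method=method, seed=seed, boundary=True)

    if method.upper() == "ML":
        b0, b1, ll, cov = _ml_fit(counts, ages, exposures)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        z = stats.norm.ppf(0.975)
        return AgeModelFit(
            sex, float(b0), float(b1),
            (float(b0 - z * se[0]), float(b0 + z * se[0])),
            (float(b1 - z * se[1]), float(b1 + z * se[1])),
            loglik=ll, loglik_null=ll_null, n_trios=len(counts),
            method="ML", seed=seed, cov=cov,
        )
    if method.upper() == "BAYES":
        if seed is None:
            raise ValueError("Bayes fit requires a seed")
        flat = _bayes_fit(counts, ages, exposures, seed)
        b0, b1 = flat.mean(axis=0)
        ll = poisson_loglik(b0, b1, counts, ages, exposures)
        return AgeModelFit(
            sex, float(b0), float(b1), hdi(flat[:, 0]), hdi(flat[:, 1]),
            loglik=ll, loglik_null=ll_null, n_trios=len(counts),
            method="Bayes", seed=seed, cov=np.cov(flat.T),
        )
    raise ValueError(f"unknown method {method!r}")


def mcfadden_r2(fit: AgeModelFit) -> float:
    """McFadden's pseudo-R^2: 1 - ll_model / ll_null."""
    if fit.loglik_null == 0:
        raise ValueError("null log-likelihood of zero")
    return 1.0 - fit.loglik / fit.loglik_null


def downsample_and_refit(
    counts, ages, exposures, target_total: int, seed: int, sex: str = "paternal",
    method: str = "ML",
) -> AgeModelFit:
    """Binomially thin per-trio counts to a target total and refit.

    Each mutation is kept independently with probability
    target_total/sum(counts), preserving the Poisson structure (thinning
    scales both intercept and slope by the keep probability in
    expectation).
    """
    counts = np.asarray(counts)
    total = int(counts.sum())
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds available {total}")
    q = target_total / total
    rng = np.random.default_rng(seed)
    thinned = counts if q == 1.0 else rng.binomial(counts.astype(int), q)
    return fit_phased_age_model(thinned, ages, exposures, sex=sex, method=method, seed=seed)


def fit_by_size_class(
    counts, ages, exposures, size_classes, sex: str = "paternal", method: str = "ML",
    seed: int | None = None,
) -> dict:
    """Independent fits per breed-size class plus a pooled fit.

    Returns {'pooled': fit, '<class>': fit, ...}; classes with no trios
    are omitted with a warning.
    """
    import warnings

    counts = np.asarray(counts)
    ages = np.asarray(ages, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    size_classes = np.asarray(size_classes)
    fits = {"pooled": fit_phased_age_model(counts, ages, exposures, sex, method, seed)}
    for cls in ("small", "intermediate", "large"):
        mask = size_classes == cls
        if not mask.any():
            warnings.warn(f"size class {cls!r} empty; omitted", stacklevel=2)
            continue
        fits[cls] = fit_phased_age_model(
            counts[mask], ages[mask], exposures[mask], sex, method, seed
        )
    return fits


def predict_rate_at_age(fit: AgeModelFit, age_years: float, max_extrapolation_age: float = 20.0):
    """Predicted phased mutation rate (per bp) at a given parental age.

    Returns (rate, (lo, hi)); a negative point prediction is truncated
    at zero and flagged by the zero lower bound.
    """
    if not 0 <= age_years <= max_extrapolation_age:
        raise ValueError(f"age {age_years} outside extrapolation guard")
    point = fit.b0 + fit.b1 * age_years
    if fit.cov is not None and np.all(np.isfinite(fit.cov)):
        var = fit.cov[0, 0] + 2 * age_years * fit.cov[0, 1] + age_years**2 * fit.cov[1, 1]
        half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    else:
        half = 0.0
    lo, hi = point - half, point + half
    if point < 0:
        return 0.0, (0.0, max(hi, 0.0))
    return float(point), (float(max(lo, 0.0)), float(hi))


def yearly_rate(
    fit_paternal: AgeModelFit,
    fit_maternal: AgeModelFit,
    mean_paternal_age: float,
    mean_maternal_age: float,
):
    """Yearly germline mutation rate (per bp per year), two approximations.

    Primary: the per-generation per-bp rate evaluated at the mean
    parental ages, divided by the mean generation interval.  Also
    reported: the slope-sum estimate (b1p + b1m)/2, the rate added per
    diploid bp when both parental ages advance one year.  Returns
    (interval_based, slope_sum).
    """
    gen_interval = (mean_paternal_age + mean_maternal_age) / 2.0
    if gen_interval <= 0:
        raise ValueError("generation interval must be positive")
    r_p = fit_paternal.b0 + fit_paternal.b1 * mean_paternal_age
    r_m = fit_maternal.b0 + fit_maternal.b1 * mean_maternal_age
    per_generation = (r_p + r_m) / 2.0
    interval_based = per_generation / gen_interval
    slope_sum = (fit_paternal.b1 + fit_maternal.b1) / 2.0
    return interval_based, slope_sum
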