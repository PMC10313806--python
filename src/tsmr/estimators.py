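"""Causal-effect estimators and sensitivity statistics for two-sample MR.

Given harmonized per-variant effects — gamma on the exposure, alpha on the
outcome, with standard errors — the estimators here combine the per-variant
Wald ratios alpha/gamma into a causal effect of the exposure on the outcome:

* Wald ratio: the single-instrument estimate alpha/gamma.
* IVW: inverse-variance weighted mean of the ratios with weights
  w_i = gamma_i^2 / se_alpha_i^2, algebraically identical to weighted least
  squares of alpha on gamma through the origin. Fixed-effect SE is
  1/sqrt(sum w); the multiplicative random-effects model inflates it by
  sqrt(Q/df) when Cochran's Q exceeds its degrees of freedom.
* MR-Egger: the same regression with a free intercept; a nonzero intercept
  estimates the average directional pleiotropic effect (valid under InSIDE),
  and the slope remains a consistent causal estimate.
* Simple / weighted median: the (weighted) median of the ratios, consistent
  when instruments carrying at least half of the weight are valid; its SE
  comes from a parametric bootstrap.
* Cochran's Q and a simplified MR-PRESSO (global RSS test plus per-variant
  outlier test) quantify heterogeneity and pleiotropic outliers.

For binary outcomes beta is a log odds ratio, so ``exp(beta)`` is the OR per
unit (1 SD for quantitative exposures) of genetically predicted exposure.
All confidence intervals use the normal 1.96 approximation; a t-based
small-sample option exists for Egger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedInstrument

Z95 = 1.96  # normal-approximation multiplier used for every 95% CI
_TINY_P = float(np.finfo(float).tiny)


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested method."""


@dataclass
class MRResult:
    """One method's causal estimate on the log-odds (beta) and OR scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    or_: float
    or_low: float
    or_high: float
    pvalue: float
    n_snp: int
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    seed: Optional[int] = None


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test across per-variant ratio estimates."""

    Q: float
    df: int
    pvalue: float


@dataclass
class PressoResult:
    """Simplified MR-PRESSO: global RSS test plus per-variant outlier test."""

    rss_observed: float
    global_p: float
    outlier_flags: np.ndarray  # per-variant boolean, Bonferroni at outlier_alpha
    outlier_p: np.ndarray
    n_sim: int
    seed: int


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    gamma = np.array([i.gamma for i in instruments], dtype=float)
    se_g = np.array([i.se_gamma for i in instruments], dtype=float)
    alpha = np.array([i.alpha for i in instruments], dtype=float)
    se_a = np.array([i.se_alpha for i in instruments], dtype=float)
    if np.any(se_a <= 0) or np.any(se_g <= 0):
        raise ValueError("all standard errors must be positive")
    return gamma, se_g, alpha, se_a


def _two_sided_p(beta: float, se: float) -> float:
    if se == 0:
        return _TINY_P
    return max(2.0 * sps.norm.sf(abs(beta) / se), _TINY_P)


def _finish(method: str, beta: float, se: float, n_snp: int, *, pvalue=None, **extras) -> MRResult:
    ci_low = beta - Z95 * se
    ci_high = beta + Z95 * se
    return MRResult(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        or_=float(np.exp(beta)),
        or_low=float(np.exp(ci_low)),
        or_high=float(np.exp(ci_high)),
        pvalue=float(_two_sided_p(beta, se) if pvalue is None else pvalue),
        n_snp=n_snp,
        **extras,
    )


def to_odds_ratio(res: MRResult) -> MRResult:
    """Re-derive the OR-scale fields from beta and se (idempotent)."""
    return replace(
        res,
        ci_low=res.beta - Z95 * res.se,
        ci_high=res.beta + Z95 * res.se,
        or_=float(np.exp(res.beta)),
        or_low=float(np.exp(res.beta - Z95 * res.se)),
        or_high=float(np.exp(res.beta + Z95 * res.se)),
    )


def wald_ratio(inst: HarmonizedInstrument, second_order: bool = False) -> MRResult:
    """Single-instrument causal estimate alpha/gamma.

    The default SE is the first-order delta method ``se_alpha/|gamma|``;
    ``second_order=True`` adds the term propagating the exposure-side
    uncertainty, ``alpha^2 se_gamma^2 / gamma^4``.
    """
    if inst.gamma == 0:
        raise ZeroDivisionError(f"{inst.variant_id}: Wald ratio undefined for gamma = 0")
    beta = inst.alpha / inst.gamma
    var = (inst.se_alpha / inst.gamma) ** 2
    if second_order:
        var += inst.alpha**2 * inst.se_gamma**2 / inst.gamma**4
    return _finish("wald_ratio", beta, float(np.sqrt(var)), 1)


def ivw(
    instruments: Sequence[HarmonizedInstrument], model: str = "fixed"
) -> MRResult:
    """Inverse-variance weighted estimate across >= 2 instruments.

    ``model`` is ``fixed`` or ``multiplicative_random_effects``; both share
    the identical point estimate, the latter scales the SE by
    ``max(1, sqrt(Q/df))``.
    """
    if len(instruments) < 2:
        raise InsufficientInstrumentsError(
            "IVW needs >= 2 instruments; use wald_ratio for a single instrument"
        )
    if model not in ("fixed", "multiplicative_random_effects"):
        raise ValueError(f"unknown IVW model {model!r}")
    gamma, _, alpha, se_a = _arrays(instruments)
    if np.any(gamma == 0):
        raise ZeroDivisionError("IVW requires all gamma != 0")
    w = gamma**2 / se_a**2
    ratios = alpha / gamma
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    name = "ivw_fixed"
    if model == "multiplicative_random_effects":
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = len(instruments) - 1
        se *= max(1.0, float(np.sqrt(q / df)))
        name = "ivw_mre"
    return _finish(name, beta, se, len(instruments))


def cochran_q(
    instruments: Sequence[HarmonizedInstrument], beta_ivw: float
) -> HeterogeneityResult:
    """Cochran's Q about ``beta_ivw`` with IVW weights; upper-tail chi-square p."""
    if len(instruments) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    gamma, _, alpha, se_a = _arrays(instruments)
    w = gamma**2 / se_a**2
    q = float(np.sum(w * (alpha / gamma - beta_ivw) ** 2))
    df = len(instruments) - 1
    return HeterogeneityResult(Q=q, df=df, pvalue=float(sps.chi2.sf(q, df)))


def mr_egger(
    instruments: Sequence[HarmonizedInstrument], t_dist: bool = False
) -> MRResult:
    """Weighted regression of alpha on gamma with a free intercept.

    Instruments are first canonically oriented to gamma >= 0 (negating both
    gamma and alpha where gamma < 0), without which the intercept has no
    interpretation. Weights are 1/se_alpha^2; coefficient covariance uses a
    multiplicative overdispersion scale bounded below by 1. ``t_dist``
    switches p-values/CIs to the t distribution with n-2 df.
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    gamma, _, alpha, se_a = _arrays(instruments)
    flip = np.where(gamma < 0, -1.0, 1.0)
    g = gamma * flip
    a = alpha * flip
    w = 1.0 / se_a**2
    # weighted normal equations for [intercept, slope]
    x = np.column_stack([np.ones(n), g])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * a)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = a - x @ coef
    scale = max(1.0, float(np.sum(w * resid**2) / (n - 2)))
    cov = scale * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    if t_dist:
        df = n - 2
        p_slope = max(2.0 * sps.t.sf(abs(slope) / se_slope, df), _TINY_P)
        p_int = max(2.0 * sps.t.sf(abs(intercept) / se_int, df), _TINY_P)
    else:
        p_slope = _two_sided_p(slope, se_slope)
        p_int = _two_sided_p(intercept, se_int)
    return _finish(
        "egger",
        slope,
        se_slope,
        n,
        pvalue=p_slope,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=float(p_int),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at the 0.5 crossing."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    hi = int(np.searchsorted(cum, 0.5))
    lo = hi - 1
    frac = (0.5 - cum[lo]) / (cum[hi] - cum[lo])
    return float(v[lo] + frac * (v[hi] - v[lo]))


def median_estimator(
    instruments: Sequence[HarmonizedInstrument],
    weighting: str = "inverse_variance",
    n_boot: int = 1000,
    *,
    seed: int,
) -> MRResult:
    """Simple or weighted median of the per-variant ratios.

    ``inverse_variance`` weights are w_i = gamma_i^2/se_alpha_i^2; ``simple``
    weights equally. The SE is the standard deviation of ``n_boot``
    parametric-bootstrap replicates (alpha_i and gamma_i redrawn from their
    normal sampling distributions, the whole estimate recomputed), so a seed
    is mandatory and results are reproducible bit-for-bit under it.
    """
    if len(instruments) < 3:
        raise InsufficientInstrumentsError("median estimators need >= 3 instruments")
    if weighting not in ("simple", "inverse_variance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    gamma, se_g, alpha, se_a = _arrays(instruments)
    if np.any(gamma == 0):
        raise ZeroDivisionError("median estimator requires all gamma != 0")

    def estimate(g: np.ndarray, a: np.ndarray) -> float:
        ratios = a / g
        if weighting == "simple":
            w = np.ones_like(ratios)
        else:
            w = g**2 / se_a**2
        return _weighted_median(ratios, w)

    beta = estimate(gamma, alpha)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        g_star = rng.normal(gamma, se_g)
        a_star = rng.normal(alpha, se_a)
        g_star[g_star == 0] = np.finfo(float).eps  # measure-zero guard
        boots[b] = estimate(g_star, a_star)
    se = float(np.std(boots, ddof=1))
    name = "simple_median" if weighting == "simple" else "weighted_median"
    return _finish(name, beta, se, len(instruments), seed=seed)


def _loo_ivw(gamma: np.ndarray, se_a: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized: element i omits instrument i.

    ``alpha`` may be 1-D (k,) or 2-D (n_sim, k); broadcasting returns the
    matching shape.
    """
    w = gamma**2 / se_a**2
    ratios = alpha / gamma
    sw = np.sum(w)
    swr = np.sum(w * ratios, axis=-1, keepdims=alpha.ndim == 2)
    return (swr - w * ratios) / (sw - w)


def presso_global(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    *,
    seed: int,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Global horizontal-pleiotropy test with per-variant outlier detection.

    The observed statistic is the weighted residual sum of squares
    ``RSS = sum_i (alpha_i - beta_{-i} gamma_i)^2 / se_alpha_i^2`` with
    ``beta_{-i}`` the IVW estimate leaving variant i out. The null
    distribution comes from ``n_sim`` parametric simulations redrawing
    alpha*_i ~ Normal(beta_{-i} gamma_i, se_alpha_i) and recomputing RSS
    (with leave-one-out estimates recomputed on the simulated data). The
    empirical global p is ``(1 + #{RSS* >= RSS_obs}) / (n_sim + 1)``;
    per-variant outlier p-values compare each observed term with its
    simulated counterparts, Bonferroni-flagged at ``outlier_alpha``.
    """
    k = len(instruments)
    if k < 4:
        raise InsufficientInstrumentsError("the pleiotropy RSS test needs >= 4 instruments")
    gamma, _, alpha, se_a = _arrays(instruments)
    if np.any(gamma == 0):
        raise ZeroDivisionError("pleiotropy RSS test requires all gamma != 0")
    w_res = 1.0 / se_a**2
    beta_loo = _loo_ivw(gamma, se_a, alpha)
    terms_obs = w_res * (alpha - beta_loo * gamma) ** 2
    rss_obs = float(np.sum(terms_obs))

    rng = np.random.default_rng(seed)
    alpha_star = rng.normal(beta_loo * gamma, se_a, size=(n_sim, k))
    beta_loo_star = _loo_ivw(gamma, se_a, alpha_star)
    terms_star = w_res * (alpha_star - beta_loo_star * gamma) ** 2
    rss_star = terms_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    outlier_p = (1 + np.sum(terms_star >= terms_obs, axis=0)) / (n_sim + 1)
    flags = outlier_p < outlier_alpha / k
    return PressoResult(
        rss_observed=rss_obs,
        global_p=global_p,
        outlier_flags=flags,
        outlier_p=outlier_p,
        n_sim=n_sim,
        seed=seed,
    )


__all__ = [
    "HeterogeneityResult",
    "InsufficientInstrumentsError",
    "MRResult",
    "PressoResult",
    "Z95",
    "cochran_q",
    "ivw",
    "median_estimator",
    "mr_egger",
    "presso_global",
    "to_odds_ratio",
    "wald_ratio",
]
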