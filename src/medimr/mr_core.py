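"""Two-sample MR estimators on a harmonized instrument set.

All estimators consume allele-aligned (beta_exp, se_exp, beta_out, se_out)
quadruples. The inverse-variance-weighted (IVW) estimate is the precision-
weighted mean of per-variant Wald ratios, equivalent to a zero-intercept
weighted regression of outcome betas on exposure betas with weights
1/se_out². MR-Egger frees the intercept (a directional-pleiotropy probe);
the weighted median is consistent when instruments carrying at least half
the weight are valid. Binary-outcome effects are log odds, so estimates
convert to odds ratios with Wald confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet, InputError

logger = logging.getLogger("medimr")

__all__ = [
    "WaldRatio",
    "MREstimate",
    "EggerResult",
    "EstimationError",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "mr_egger",
    "weighted_median",
    "estimate_to_or",
]


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass(frozen=True)
class WaldRatio:
    """Per-variant causal estimate beta_out/beta_exp with first-order SE."""

    variant_id: str
    ratio: float
    se: float

    @property
    def weight(self) -> float:
        return self.se**-2


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate with its odds-ratio representation."""

    method: str
    k: int
    beta: float
    se: float
    pvalue: float
    or_: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pvalue: float


def estimate_to_or(beta: float, se: float, alpha: float = 0.05) -> tuple[float, float, float]:
    """(OR, CI low, CI high): exp(beta) with a Wald interval on the log scale."""
    if se <= 0:
        raise InputError("se must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _package(method: str, k: int, beta: float, se: float, pvalue: float,
             alpha: float = 0.05) -> MREstimate:
    or_, lo, hi = estimate_to_or(beta, se, alpha)
    return MREstimate(method, k, float(beta), float(se), float(pvalue), or_, lo, hi)


def wald_ratio(pair) -> WaldRatio:
    """Single-variant ratio estimate from a harmonized pair.

    ``pair`` is any object with beta_exp, se_out, beta_out (and
    variant_id) attributes, e.g. a row of ``HarmonizedSet.pairs``.
    """
    beta_exp = float(pair.beta_exp)
    if beta_exp == 0.0:
        raise EstimationError(f"degenerate instrument {pair.variant_id}: beta_exp = 0")
    return WaldRatio(
        variant_id=str(pair.variant_id),
        ratio=float(pair.beta_out) / beta_exp,
        se=float(pair.se_out) / abs(beta_exp),
    )


def wald_ratios(hset: HarmonizedSet) -> list[WaldRatio]:
    return [wald_ratio(row) for row in hset.pairs.itertuples(index=False)]


def _check(hset: HarmonizedSet, k_min: int, method: str) -> None:
    if hset.k < k_min:
        raise EstimationError(f"{method} needs at least {k_min} instruments, got {hset.k}")
    if (hset.pairs["beta_exp"] == 0).any():
        raise EstimationError(f"{method}: instrument with beta_exp = 0")


def ivw_q(hset: HarmonizedSet) -> float:
    """Cochran Q of the fixed-effect IVW fit (ratio scale)."""
    bx, _, by, so = hset.arrays()
    ratios = by / bx
    w = bx**2 / so**2
    beta = np.sum(w * ratios) / np.sum(w)
    return float(np.sum(w * (ratios - beta) ** 2))


def ivw(
    hset: HarmonizedSet,
    effects_model: str = "multiplicative_random",
    alpha: float = 0.05,
) -> MREstimate:
    """Inverse-variance-weighted estimate.

    With weights w_j = beta_exp_j²/se_out_j² on Wald ratios: the point
    estimate is the weighted mean, se_fixed = (Σw)^(−1/2). Under the
    multiplicative random-effects model the SE is inflated by
    max(1, sqrt(Q/(k−1))); p-values use the normal reference.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise InputError(f"unknown effects_model {effects_model!r}")
    _check(hset, 1, "ivw")
    bx, _, by, so = hset.arrays()
    k = hset.k
    ratios = by / bx
    w = bx**2 / so**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    method = f"ivw_{'fixed' if effects_model == 'fixed' else 'mre'}"
    if effects_model == "multiplicative_random":
        if k == 1:
            logger.info("ivw: k=1, multiplicative_random falls back to fixed")
            method = "ivw_fixed"
        else:
            q = float(np.sum(w * (ratios - beta) ** 2))
            se *= max(1.0, np.sqrt(q / (k - 1)))
    pvalue = float(2.0 * stats.norm.sf(abs(beta / se)))
    return _package(method, k, beta, se, max(pvalue, np.nextafter(0, 1)), alpha)


def mr_egger(hset: HarmonizedSet, alpha: float = 0.05) -> EggerResult:
    """MR-Egger regression.

    Pairs are oriented so beta_exp > 0 (both betas flipped otherwise),
    then outcome betas are regressed on exposure betas with weights
    1/se_out² and a free intercept. Slope and intercept SEs carry the
    multiplicative heterogeneity inflation max(1, sqrt(Q/(k−2)));
    p-values use the t reference with k − 2 degrees of freedom.
    """
    _check(hset, 3, "mr_egger")
    bx, _, by, so = hset.arrays()
    k = hset.k
    flip = np.sign(bx)
    x = bx * flip
    y = by * flip
    w = so**-2.0

    sw = np.sum(w)
    sx = np.sum(w * x)
    sy = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    denom = sw * sxx - sx**2
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sxx * sy - sx * sxy) / denom

    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (k - 2)))
    se_slope = np.sqrt(sw / denom) * scale
    se_int = np.sqrt(sxx / denom) * scale

    df = k - 2
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df))
    return EggerResult(
        slope=_package("egger", k, slope, se_slope, max(p_slope, np.nextafter(0, 1)), alpha),
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pvalue=max(p_int, float(np.nextafter(0, 1))),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    p = weights[order] / np.sum(weights)
    s = np.cumsum(p) - p / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    The point estimate interpolates the sorted Wald ratios at the point
    where the midpoint-adjusted cumulative weight crosses one half. The
    SE resamples each (beta_exp, beta_out) from normals at their SEs,
    recomputes the estimate ``n_boot`` times, and takes the standard
    deviation; the seed is mandatory so results are reproducible.
    """
    _check(hset, 3, "weighted_median")
    if seed is None:
        raise InputError("weighted_median requires an explicit seed")
    bx, sx, by, so = hset.arrays()
    k = hset.k
    ratios = by / bx
    w = bx**2 / so**2
    beta = _weighted_median_point(ratios, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(k)
        bys = by + so * rng.standard_normal(k)
        bxs = np.where(bxs == 0.0, np.finfo(float).tiny, bxs)
        boots[b] = _weighted_median_point(bys / bxs, bxs**2 / so**2)
    se = float(np.std(boots, ddof=1))
    pvalue = float(2.0 * stats.norm.sf(abs(beta / se))) if se > 0 else 1.0
    return _package("weighted_median", k, beta, se, max(pvalue, np.nextafter(0, 1)), alpha)
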