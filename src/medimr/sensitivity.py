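"""Heterogeneity, pleiotropy and influence diagnostics for an MR fit.

Cochran's Q measures between-instrument heterogeneity of the fitted
model (IVW: one slope, df = k−1; Egger: slope plus intercept, df = k−2)
against a chi-square reference. Leave-one-out re-estimates IVW with each
instrument omitted; single-SNP reports each Wald ratio with its own
normal-tail p-value. The Egger intercept itself (the pleiotropy probe)
lives on :class:`~medimr.mr_core.EggerResult`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr_core import EstimationError, ivw, mr_egger
from .sumstats import HarmonizedSet

__all__ = [
    "HeterogeneityReport",
    "PleiotropyReport",
    "cochran_q_from_fitted",
    "cochran_q",
    "pleiotropy_test",
    "leave_one_out",
    "single_snp",
]


@dataclass(frozen=True)
class HeterogeneityReport:
    method: str  # "ivw" or "egger"
    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyReport:
    intercept: float
    se: float
    pvalue: float


def cochran_q_from_fitted(
    observed: np.ndarray,
    fitted: np.ndarray,
    weights: np.ndarray,
    df: int,
    method: str = "ivw",
) -> HeterogeneityReport:
    """Q = Σ w_j (observed_j − fitted_j)² referred to chi-square(df)."""
    q = float(np.sum(np.asarray(weights) * (np.asarray(observed) - np.asarray(fitted)) ** 2))
    return HeterogeneityReport(method, q, int(df), float(stats.chi2.sf(q, df)))


def cochran_q(hset: HarmonizedSet, method: str = "ivw") -> HeterogeneityReport:
    """Heterogeneity of the IVW (df = k−1) or Egger (df = k−2) fit.

    Residuals are taken on the outcome-beta scale with weights 1/se_out²,
    which for IVW coincides with the ratio-scale form using weights
    beta_exp²/se_out².
    """
    bx, _, by, so = hset.arrays()
    k = hset.k
    w = so**-2.0
    if method == "ivw":
        if k < 2:
            raise EstimationError("cochran_q(ivw) needs at least 2 instruments")
        beta = ivw(hset, effects_model="fixed").beta
        return cochran_q_from_fitted(by, beta * bx, w, k - 1, "ivw")
    if method == "egger":
        if k < 3:
            raise EstimationError("cochran_q(egger) needs at least 3 instruments")
        res = mr_egger(hset)
        flip = np.sign(bx)
        fitted = flip * (res.intercept + res.slope.beta * bx * flip)
        return cochran_q_from_fitted(by, fitted, w, k - 2, "egger")
    raise EstimationError(f"unknown heterogeneity method {method!r}")


def pleiotropy_test(hset: HarmonizedSet) -> PleiotropyReport:
    """Egger-intercept test for directional horizontal pleiotropy."""
    res = mr_egger(hset)
    return PleiotropyReport(res.intercept, res.intercept_se, res.intercept_pvalue)


def leave_one_out(
    hset: HarmonizedSet,
    alpha: float = 0.05,
    effects_model: str = "multiplicative_random",
) -> pd.DataFrame:
    """IVW re-estimated with each instrument omitted in turn.

    Returns one row per omitted variant with the reduced estimate plus
    flags for omissions that flip the sign of beta or move the p-value
    across ``alpha`` relative to the full-set estimate.
    """
    if hset.k < 2:
        raise EstimationError("leave_one_out needs at least 2 instruments")
    full = ivw(hset, effects_model=effects_model)
    rows = []
    for i in range(hset.k):
        reduced = HarmonizedSet(
            hset.exposure_meta,
            hset.outcome_meta,
            hset.pairs.drop(index=i).reset_index(drop=True),
        )
        est = ivw(reduced, effects_model=effects_model)
        rows.append(
            {
                "omitted_variant": hset.pairs.at[i, "variant_id"],
                "k": est.k,
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "sign_change": bool(np.sign(est.beta) != np.sign(full.beta)),
                "crosses_alpha": bool((est.pvalue < alpha) != (full.pvalue < alpha)),
            }
        )
    return pd.DataFrame(rows)


def single_snp(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-variant Wald ratios with normal-tail p-values."""
    if hset.k < 1:
        raise EstimationError("single_snp needs at least 1 instrument")
    bx, _, by, so = hset.arrays()
    ratio = by / bx
    se = so / np.abs(bx)
    p = 2.0 * stats.norm.sf(np.abs(ratio / se))
    return pd.DataFrame(
        {
            "variant_id": hset.pairs["variant_id"],
            "ratio": ratio,
            "se": se,
            "pvalue": p,
        }
    )
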