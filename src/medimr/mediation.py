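"""Screening cascade and product-of-coefficients mediation decomposition.

The cascade mirrors a three-cohort two-step MR design: exposures (gut
microbiota taxa) and candidate mediators (serum metabolites) are each
screened against the outcome by IVW; for every significant exposure ×
significant mediator pair the exposure→mediator path is estimated, and
qualifying paths are decomposed as

    beta12 = beta1 × beta2        (indirect, through the mediator)
    beta_dir = beta_total − beta12 (direct remainder)

where beta_total is the exposure→outcome IVW effect, beta1 the
exposure→mediator effect and beta2 the mediator→outcome effect.
Screening uses raw p-values at alpha (no multiplicity correction) by
default, with an optional Benjamini-Hochberg switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .iv_selection import LDInfo, select_instruments
from .mr_core import EstimationError, MREstimate, ivw
from .sumstats import ConfigError, HarmonizedSet, SummaryStatsTable, harmonize

logger = logging.getLogger("medimr")

__all__ = [
    "MediationRecord",
    "CascadeConfig",
    "screen_significant",
    "decompose",
    "run_cascade",
]


@dataclass(frozen=True)
class MediationRecord:
    """One exposure→mediator→outcome decomposition.

    ``mediator_id`` is None when no mediator qualified; then beta12 = 0
    and beta_dir = beta_total. The underlying IVW estimates are kept for
    odds-ratio reporting.
    """

    exposure_id: str
    mediator_id: str | None
    beta_total: float
    beta1: float
    beta2: float
    beta12: float
    beta_dir: float
    est_total: MREstimate | None = None
    est1: MREstimate | None = None
    est2: MREstimate | None = None

    @property
    def proportion_mediated(self) -> float:
        """beta12 / beta_total — a derived convenience, not a primary output."""
        return self.beta12 / self.beta_total if self.beta_total != 0 else float("nan")


@dataclass
class CascadeConfig:
    """Thresholds governing the screening cascade."""

    alpha_screen: float = 0.05
    require_mediator_alpha: float = 0.05
    iv_p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 500.0
    f_min: float = 10.0
    palindrome_window: float = 0.08
    effects_model: str = "multiplicative_random"
    bh_correction: bool = False
    exclusions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_screen", "require_mediator_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 and v != 1.0:
                raise ConfigError(f"{name} must be in (0,1], got {v}")


def screen_significant(
    estimates: Mapping[str, MREstimate],
    alpha: float,
    bh: bool = False,
) -> dict[str, MREstimate]:
    """Subset of estimates significant at ``alpha``, order preserved.

    With ``bh=True`` the comparison uses Benjamini-Hochberg adjusted
    p-values instead of raw ones.
    """
    if not estimates:
        return {}
    if bh:
        from .enrichment import bh_fdr

        adj = bh_fdr([est.pvalue for est in estimates.values()])
        return {
            tid: est
            for (tid, est), q in zip(estimates.items(), adj)
            if q < alpha
        }
    return {tid: est for tid, est in estimates.items() if est.pvalue < alpha}


def decompose(beta_total: float, beta1: float, beta2: float) -> tuple[float, float]:
    """(beta12, beta_dir) = (beta1·beta2, beta_total − beta1·beta2)."""
    beta12 = beta1 * beta2
    return beta12, beta_total - beta12


def _mr_on_outcome(
    trait_table: SummaryStatsTable,
    outcome_table: SummaryStatsTable,
    ld: LDInfo,
    config: CascadeConfig,
) -> tuple[MREstimate, HarmonizedSet]:
    """Select instruments for one trait and estimate its effect on the outcome."""
    instruments = select_instruments(
        trait_table,
        ld,
        p_threshold=config.iv_p_threshold,
        clump_r2=config.clump_r2,
        clump_kb=config.clump_kb,
        f_min=config.f_min,
        exclusions=config.exclusions,
    )
    if len(instruments) == 0:
        raise EstimationError(f"no instruments survive selection for {trait_table.meta.trait_id}")
    iv_table = instruments.as_table(trait_table.meta)
    hset = harmonize(iv_table, outcome_table, config.palindrome_window)
    return ivw(hset, effects_model=config.effects_model), hset


def run_cascade(
    exposure_tables: Mapping[str, SummaryStatsTable],
    mediator_tables: Mapping[str, SummaryStatsTable],
    outcome_table: SummaryStatsTable,
    ld: LDInfo,
    config: CascadeConfig | None = None,
) -> tuple[list[MediationRecord], dict]:
    """Run the full screening cascade.

    Stages: (1) every exposure is screened against the outcome; (2) every
    mediator is screened against the outcome; (3) for each significant
    exposure, each significant mediator is tested as exposure→mediator;
    (4) qualifying paths are decomposed, and exposures with no qualifying
    mediator emit a mediator-less record carrying beta_total alone.

    Returns the mediation records plus a details dict with the per-stage
    estimates and harmonized sets (for sensitivity reporting).
    """
    config = config or CascadeConfig()
    details: dict = {
        "exposure_estimates": {},
        "mediator_estimates": {},
        "exposure_hsets": {},
        "mediator_hsets": {},
        "link_estimates": {},
    }

    for tid, table in exposure_tables.items():
        try:
            est, hset = _mr_on_outcome(table, outcome_table, ld, config)
        except (EstimationError, ValueError) as exc:
            raise type(exc)(f"stage=exposure_screen pair=({tid}, outcome): {exc}") from exc
        details["exposure_estimates"][tid] = est
        details["exposure_hsets"][tid] = hset

    for tid, table in mediator_tables.items():
        try:
            est, hset = _mr_on_outcome(table, outcome_table, ld, config)
        except (EstimationError, ValueError) as exc:
            raise type(exc)(f"stage=mediator_screen pair=({tid}, outcome): {exc}") from exc
        details["mediator_estimates"][tid] = est
        details["mediator_hsets"][tid] = hset

    sig_exposures = screen_significant(
        details["exposure_estimates"], config.alpha_screen, bh=config.bh_correction
    )
    sig_mediators = screen_significant(
        details["mediator_estimates"], config.alpha_screen, bh=config.bh_correction
    )
    logger.info(
        "cascade: %d/%d exposures and %d/%d mediators significant at alpha=%g",
        len(sig_exposures), len(exposure_tables),
        len(sig_mediators), len(mediator_tables), config.alpha_screen,
    )

    records: list[MediationRecord] = []
    for exp_id, est_total in sig_exposures.items():
        found_mediator = False
        for med_id, est2 in sig_mediators.items():
            try:
                est1, _ = _mr_on_outcome(
                    exposure_tables[exp_id], mediator_tables[med_id], ld, config
                )
            except (EstimationError, ValueError) as exc:
                raise type(exc)(f"stage=link pair=({exp_id}, {med_id}): {exc}") from exc
            details["link_estimates"][(exp_id, med_id)] = est1
            if est1.pvalue < config.require_mediator_alpha:
                beta12, beta_dir = decompose(est_total.beta, est1.beta, est2.beta)
                records.append(
                    MediationRecord(
                        exposure_id=exp_id,
                        mediator_id=med_id,
                        beta_total=est_total.beta,
                        beta1=est1.beta,
                        beta2=est2.beta,
                        beta12=beta12,
                        beta_dir=beta_dir,
                        est_total=est_total,
                        est1=est1,
                        est2=est2,
                    )
                )
                found_mediator = True
        if not found_mediator:
            records.append(
                MediationRecord(
                    exposure_id=exp_id,
                    mediator_id=None,
                    beta_total=est_total.beta,
                    beta1=0.0,
                    beta2=0.0,
                    beta12=0.0,
                    beta_dir=est_total.beta,
                    est_total=est_total,
                )
            )
    return records, details


def records_to_frame(records: Sequence[MediationRecord]) -> pd.DataFrame:
    """Mediation records as a report-ready DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "exposure": r.exposure_id,
                "beta_total": r.beta_total,
                "beta_1": r.beta1,
                "or_1": r.est1.or_ if r.est1 else float("nan"),
                "or_1_ci_low": r.est1.ci_low if r.est1 else float("nan"),
                "or_1_ci_high": r.est1.ci_high if r.est1 else float("nan"),
                "mediator": r.mediator_id or "",
                "beta_2": r.beta2,
                "or_2": r.est2.or_ if r.est2 else float("nan"),
                "or_2_ci_low": r.est2.ci_low if r.est2 else float("nan"),
                "or_2_ci_high": r.est2.ci_high if r.est2 else float("nan"),
                "beta_12": r.beta12,
                "beta_dir": r.beta_dir,
                "proportion_mediated": r.proportion_mediated,
            }
        )
    return pd.DataFrame(rows)
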