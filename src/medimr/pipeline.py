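"""End-to-end orchestration: config, logging, and report generation.

``run_full`` executes exposure→outcome screening, mediator→outcome
screening, the mediation cascade and (optionally) metabolite-set
enrichment, and writes report tables as TSV: per-trait MR estimates with
heterogeneity/pleiotropy columns, volcano-ready values (log2 OR,
−log10 p), mediation decompositions, leave-one-out and single-variant
diagnostics, and a Sankey-ready edge list. Display columns are rounded
(OR to 2 decimals, betas and p to 4); full-precision parallels keep the
machine-readable values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from .mediation import CascadeConfig, run_cascade, records_to_frame
from .mr_core import EstimationError, mr_egger, weighted_median
from .sensitivity import cochran_q, leave_one_out, single_snp
from .sumstats import ConfigError, SummaryStatsTable, TraitMeta, read_sumstats
from .iv_selection import LDInfo

logger = logging.getLogger("medimr")

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    exposures: Mapping[str, str]        # trait_id -> sumstats path
    mediators: Mapping[str, str]
    outcome: str
    ld: str
    out_dir: str
    exposure_n: int | None = None
    mediator_n: int | None = None
    outcome_n: int | None = None
    outcome_n_case: int | None = None
    gmt: str | None = None
    iv_p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: float = 500.0
    f_min: float = 10.0
    alpha_screen: float = 0.05
    palindrome_window: float = 0.08
    effects_model: str = "multiplicative_random"
    wm_n_boot: int = 1000
    wm_seed: int | None = None
    exclusions: Mapping[str, str] = field(default_factory=dict)
    fail_on_empty: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, out_dir: str | Path,
                    **overrides) -> "RunConfig":
        """Configuration pointing at a simulated fixture bundle."""
        import json

        bundle_dir = Path(bundle_dir)
        truth = json.loads((bundle_dir / "truth.json").read_text())
        cfg = dict(
            exposures={"exposure_sim": str(bundle_dir / "exposure.tsv")},
            mediators={"mediator_sim": str(bundle_dir / "mediator.tsv")},
            outcome=str(bundle_dir / "outcome.tsv"),
            ld=str(bundle_dir / "ld.tsv"),
            out_dir=str(out_dir),
            exposure_n=truth["n_exp"],
            mediator_n=truth["n_med"],
            outcome_n=truth["n_out"],
            outcome_n_case=int(round(truth["case_fraction"] * truth["n_out"])),
            wm_seed=truth["seed"],
        )
        cfg.update(overrides)
        return cls(**cfg)


def _load(path: str, trait_id: str, role: str, n: int | None,
          n_case: int | None = None) -> SummaryStatsTable:
    trait_type = "binary" if role == "outcome" and n_case else "continuous"
    n_control = (n - n_case) if (n and n_case) else None
    meta = TraitMeta(trait_id, trait_id, role, trait_type, n,
                     n_case=n_case, n_control=n_control)
    return read_sumstats(path, meta)


def _round_cols(df: pd.DataFrame) -> pd.DataFrame:
    """Apply display rounding, keeping full precision in *_full columns."""
    out = df.copy()
    for col in df.columns:
        if col.startswith(("or", "ci_")) or col in ("or_1", "or_2"):
            out[col + "_full"] = df[col]
            out[col] = df[col].round(2)
        elif col.startswith(("beta", "pvalue", "intercept", "q")) or col in (
            "se", "proportion_mediated",
        ):
            out[col + "_full"] = df[col]
            out[col] = df[col].round(4)
    return out


def _mr_table(details_est: Mapping, hsets: Mapping, config: RunConfig) -> pd.DataFrame:
    """Per-trait three-method MR rows with heterogeneity/pleiotropy columns."""
    rows = []
    for tid, est in details_est.items():
        hset = hsets[tid]
        rows.append(
            dict(trait=tid, nsnp=est.k, method=est.method, beta=est.beta, se=est.se,
                 or_=est.or_, ci_low=est.ci_low, ci_high=est.ci_high, pvalue=est.pvalue,
                 q=np.nan, q_pvalue=np.nan, intercept=np.nan, intercept_pvalue=np.nan)
        )
        if hset.k >= 3:
            try:
                egger = mr_egger(hset)
                het_ivw = cochran_q(hset, "ivw")
                het_egg = cochran_q(hset, "egger")
                rows[-1].update(q=het_ivw.q, q_pvalue=het_ivw.pvalue,
                                intercept=egger.intercept,
                                intercept_pvalue=egger.intercept_pvalue)
                s = egger.slope
                rows.append(
                    dict(trait=tid, nsnp=s.k, method="egger", beta=s.beta, se=s.se,
                         or_=s.or_, ci_low=s.ci_low, ci_high=s.ci_high, pvalue=s.pvalue,
                         q=het_egg.q, q_pvalue=het_egg.pvalue,
                         intercept=np.nan, intercept_pvalue=np.nan)
                )
                wm = weighted_median(hset, n_boot=config.wm_n_boot, seed=config.wm_seed)
                rows.append(
                    dict(trait=tid, nsnp=wm.k, method="weighted_median", beta=wm.beta,
                         se=wm.se, or_=wm.or_, ci_low=wm.ci_low, ci_high=wm.ci_high,
                         pvalue=wm.pvalue, q=np.nan, q_pvalue=np.nan,
                         intercept=np.nan, intercept_pvalue=np.nan)
                )
            except EstimationError as exc:
                logger.warning("trait=%s secondary methods skipped: %s", tid, exc)
    return pd.DataFrame(rows)


def _volcano(details_est: Mapping) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": list(details_est),
            "log2_or": [np.log2(e.or_) for e in details_est.values()],
            "neg_log10_p": [-np.log10(e.pvalue) for e in details_est.values()],
        }
    )


def run_full(config: RunConfig) -> tuple[list, dict]:
    """Run the full pipeline; returns (mediation records, output paths)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        for key, val in dataclasses.asdict(config).items():
            logger.info("config %s=%s", key, val)

        if config.wm_seed is None:
            raise ConfigError("wm_seed is required (weighted median must be reproducible)")

        exposures = {
            tid: _load(p, tid, "exposure", config.exposure_n)
            for tid, p in config.exposures.items()
        }
        mediators = {
            tid: _load(p, tid, "mediator", config.mediator_n)
            for tid, p in config.mediators.items()
        }
        outcome = _load(config.outcome, "outcome", "outcome", config.outcome_n,
                        config.outcome_n_case)
        ld = LDInfo.read_tsv(config.ld)

        cascade_cfg = CascadeConfig(
            alpha_screen=config.alpha_screen,
            require_mediator_alpha=config.alpha_screen,
            iv_p_threshold=config.iv_p_threshold,
            clump_r2=config.clump_r2,
            clump_kb=config.clump_kb,
            f_min=config.f_min,
            palindrome_window=config.palindrome_window,
            effects_model=config.effects_model,
            exclusions=dict(config.exclusions),
        )
        records, details = run_cascade(exposures, mediators, outcome, ld, cascade_cfg)

        paths: dict[str, Path] = {}

        def write(name: str, df: pd.DataFrame, rounded: bool = True) -> None:
            path = out_dir / name
            (_round_cols(df) if rounded else df).to_csv(path, sep="\t", index=False)
            paths[name] = path

        write("mr_exposure_outcome.tsv",
              _mr_table(details["exposure_estimates"], details["exposure_hsets"], config))
        write("mr_mediator_outcome.tsv",
              _mr_table(details["mediator_estimates"], details["mediator_hsets"], config))
        write("volcano_exposure.tsv", _volcano(details["exposure_estimates"]), rounded=False)
        write("volcano_mediator.tsv", _volcano(details["mediator_estimates"]), rounded=False)
        write("mediation.tsv", records_to_frame(records))

        loo_frames, snp_frames = [], []
        for group in ("exposure_hsets", "mediator_hsets"):
            for tid, hset in details[group].items():
                if hset.k >= 2:
                    loo = leave_one_out(hset, alpha=config.alpha_screen,
                                        effects_model=config.effects_model)
                    loo.insert(0, "trait", tid)
                    loo_frames.append(loo)
                snp = single_snp(hset)
                snp.insert(0, "trait", tid)
                snp_frames.append(snp)
        write("leave_one_out.tsv", pd.concat(loo_frames, ignore_index=True)
              if loo_frames else pd.DataFrame())
        write("single_snp.tsv", pd.concat(snp_frames, ignore_index=True)
              if snp_frames else pd.DataFrame(), rounded=False)

        sankey = [
            {"source": r.exposure_id, "target": r.mediator_id or "outcome",
             "weight": r.beta12 if r.mediator_id else r.beta_total}
            for r in records
        ] + [
            {"source": r.mediator_id, "target": "outcome", "weight": r.beta2}
            for r in records if r.mediator_id
        ]
        write("sankey_edges.tsv",
              pd.DataFrame(sankey, columns=["source", "target", "weight"]), rounded=False)

        if config.gmt:
            library = enr.load_gmt(config.gmt)
            sig_meds = [tid for r in records if r.mediator_id for tid in [r.mediator_id]]
            if sig_meds:
                ora_records = enr.ora(sig_meds, library)
                write("enrichment.tsv", enr.records_to_frame(ora_records))
                write("enrichment_network.tsv", enr.enrichment_network(ora_records),
                      rounded=False)

        n_mediated = sum(1 for r in records if r.mediator_id)
        logger.info("run complete: %d mediation records (%d with a mediator)",
                    len(records), n_mediated)
        if config.fail_on_empty and not records:
            raise EstimationError("no significant exposure at alpha_screen (fail_on_empty)")
        return records, paths
    finally:
        logger.removeHandler(handler)
        handler.close()
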