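"""Synthetic GWAS summary-statistic triplets with known causal structure.

The generator emulates the shapes of three linked summary-statistic
tables — a continuous exposure (a microbial taxon abundance), a
continuous mediator (a serum metabolite) and a binary outcome on the
log-odds scale (a rare disease) — under the standard instrumental-model
assumptions. Per instrument j:

    gamma_j   ~ Normal(0, gamma_sd²), resampled until its exposure
                p-value clears the instrument threshold (usable IVs
                by construction)
    alpha_j   = beta1 · gamma_j                     (mediator path)
    Gamma_j   = beta_dir · gamma_j + beta2 · alpha_j + pi_j
    pi_j      ~ Normal(pleiotropy_mean, pleiotropy_sd²)

so the planted total effect is beta_total = beta_dir + beta1·beta2.
The mediator additionally carries ``k_med_instruments`` loci of its own
(effects delta ~ Normal(0, delta_sd²), resampled to clear the threshold
at n_med, null on the exposure, beta2·delta on the outcome), emulating a
metabolite GWAS with an independent genetic architecture — these are
the instruments of the mediator→outcome leg.
Standard errors follow the allele-frequency closed form
se = (2·n·eaf(1−eaf))^(−1/2); for the binary outcome n is replaced by
the effective size v·n with v = case_fraction·(1 − case_fraction),
preserving the scale of a rare-disease GWAS without individual-level
simulation. LD blocks add tag variants correlated with each causal lead
(cross-block r² = 0) as a clumping substrate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .iv_selection import LDInfo
from .sumstats import ConfigError, SummaryStatsTable, TraitMeta, read_sumstats

__all__ = [
    "TripletTruth",
    "LDBlockSpec",
    "simulate_triplet",
    "write_fixture_bundle",
    "read_fixture_bundle",
]

# non-palindromic allele pairs only: harmonization keeps every variant
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

_TINY_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class TripletTruth:
    """Generative parameters of one exposure–mediator–outcome system.

    Defaults echo the cohort scales of the motivating study design:
    exposure GWAS n = 18,340 (16S microbiome consortium scale), mediator
    GWAS n = 8299 (serum metabolome cohort scale), outcome GWAS
    n = 197,611 with case fraction 0.0094 (1866 cases). The instrument
    count defaults to 10, near the per-taxon median of such screens.
    ``gamma_sd`` is scaled so that taxon-SNP effects on the mediator
    (beta1·gamma) stay below the instrument threshold at n_med: the
    taxon and metabolite instrument sets remain disjoint, as in the
    emulated design.
    """

    seed: int
    k_instruments: int = 10
    gamma_sd: float = 0.08
    beta1: float = 0.3
    beta2: float = 0.5
    beta_dir: float = 0.2
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exp: int = 18340
    n_med: int = 8299
    n_out: int = 197611
    case_fraction: float = 0.0094
    eaf_range: tuple[float, float] = (0.1, 0.9)
    instrument_p_threshold: float = 1e-5
    orient_positive: bool = True
    max_resample: int = 1000
    k_med_instruments: int = 10
    delta_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.k_instruments < 1:
            raise ConfigError("k_instruments must be >= 1")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ConfigError("sd parameters must be >= 0")
        if not 0 < self.case_fraction < 1:
            raise ConfigError("case_fraction must be in (0,1)")

    @property
    def beta_total(self) -> float:
        return self.beta_dir + self.beta1 * self.beta2


@dataclass(frozen=True)
class LDBlockSpec:
    """Block-diagonal LD layout: ``block_size`` variants per block share
    r² = ``r2_within``; cross-block r² is 0. ``n_blocks=None`` means one
    block per instrument."""

    n_blocks: int | None = None
    block_size: int = 3
    r2_within: float = 0.64
    spacing_kb: float = 25.0

    def __post_init__(self) -> None:
        if self.block_size < 1:
            raise ConfigError("block_size must be >= 1")
        if not 0.0 <= self.r2_within < 1.0:
            raise ConfigError("r2_within must be in [0,1)")


def _se(n: float, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _TINY_P)


def simulate_triplet(
    truth: TripletTruth,
    blocks: LDBlockSpec | None = None,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable, LDInfo, TripletTruth]:
    """Generate (exposure, mediator, outcome) tables plus LD information.

    All randomness derives from ``truth.seed``. A fifth of the variants
    are written to the outcome table with swapped allele columns (beta
    negated, EAF mirrored) so that harmonization is exercised end to end.
    """
    blocks = blocks or LDBlockSpec()
    rng = np.random.default_rng(truth.seed)
    k = truth.k_instruments
    n_blocks = blocks.n_blocks if blocks.n_blocks is not None else k
    if n_blocks < k:
        raise ConfigError(f"n_blocks={n_blocks} < k_instruments={k}")

    eaf_lo, eaf_hi = truth.eaf_range
    v_out = truth.case_fraction * (1.0 - truth.case_fraction)
    n_out_eff = v_out * truth.n_out
    r_tag = float(np.sqrt(blocks.r2_within))

    # --- causal leads -----------------------------------------------------
    z_min = stats.norm.isf(truth.instrument_p_threshold / 2.0)

    def draw_cleared(sd: float, se: float, what: str) -> float:
        for _ in range(truth.max_resample):
            g = rng.normal(0.0, sd)
            if abs(g) / se > z_min:
                return g
        raise ConfigError(
            f"{what} effect sd={sd} too small to clear "
            f"p<{truth.instrument_p_threshold} after {truth.max_resample} attempts"
        )

    eaf_lead = rng.uniform(eaf_lo, eaf_hi, size=k)
    se_exp_lead = _se(truth.n_exp, eaf_lead)
    gamma = np.array(
        [draw_cleared(truth.gamma_sd, se_exp_lead[j], "exposure instrument")
         for j in range(k)]
    )
    if truth.orient_positive:
        gamma = np.abs(gamma)

    alpha_true = truth.beta1 * gamma
    pi = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, size=k)
    gamma_out_true = truth.beta_dir * gamma + truth.beta2 * alpha_true + pi

    # --- assemble variants: exposure blocks, then mediator-own blocks -----
    rows_exp, rows_med, rows_out, ld_pairs = [], [], [], []
    k_med = truth.k_med_instruments
    for b in range(n_blocks + k_med):
        chrom = str(b % 22 + 1)
        base_pos = (b // 22) * 10_000_000 + 1_000_000
        exposure_block = b < n_blocks
        is_causal = b < k
        med_own = not exposure_block
        eaf_b = eaf_lead[b] if is_causal else rng.uniform(eaf_lo, eaf_hi)
        se_med_lead = float(_se(truth.n_med, np.array(eaf_b)))
        delta = (
            (np.abs(draw_cleared(truth.delta_sd, se_med_lead, "mediator instrument"))
             if truth.orient_positive
             else draw_cleared(truth.delta_sd, se_med_lead, "mediator instrument"))
            if med_own
            else 0.0
        )
        block_ids = []
        for t in range(blocks.block_size):
            vid = f"rs{(b + 1) * 1000 + t}"
            block_ids.append(vid)
            ea, oa = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            pos = base_pos + int(t * blocks.spacing_kb * 1000)
            scale = 1.0 if t == 0 else r_tag
            if is_causal:
                g_true = scale * gamma[b]
                a_true = scale * alpha_true[b]
                o_true = scale * gamma_out_true[b]
            elif med_own:
                g_true = 0.0
                a_true = scale * delta
                o_true = truth.beta2 * scale * delta
            else:
                g_true = a_true = o_true = 0.0

            se_e = float(_se(truth.n_exp, np.array(eaf_b)))
            se_m = float(_se(truth.n_med, np.array(eaf_b)))
            se_o = float(_se(n_out_eff, np.array(eaf_b)))
            # resampled lead draws already are the observed estimates, so
            # leads carry no extra noise on their own trait; everything
            # else adds sampling noise at its SE
            b_e = g_true if (is_causal and t == 0) else g_true + rng.normal(0.0, se_e)
            b_m = a_true if (med_own and t == 0) else a_true + rng.normal(0.0, se_m)
            b_o = o_true + rng.normal(0.0, se_o)

            common = dict(
                variant_id=vid, chromosome=chrom, position=pos,
                effect_allele=ea, other_allele=oa,
            )
            rows_exp.append(
                dict(common, eaf=eaf_b, beta=b_e, se=se_e,
                     pvalue=float(_pvals(np.array(b_e), np.array(se_e))),
                     n=truth.n_exp)
            )
            rows_med.append(
                dict(common, eaf=eaf_b, beta=b_m, se=se_m,
                     pvalue=float(_pvals(np.array(b_m), np.array(se_m))),
                     n=truth.n_med)
            )
            out_row = dict(common, eaf=eaf_b, beta=b_o, se=se_o,
                           pvalue=float(_pvals(np.array(b_o), np.array(se_o))),
                           n=truth.n_out)
            if rng.random() < 0.2:  # swapped allele coding; harmonization must undo
                out_row["effect_allele"], out_row["other_allele"] = oa, ea
                out_row["beta"] = -out_row["beta"]
                out_row["eaf"] = 1.0 - out_row["eaf"]
            rows_out.append(out_row)
        for i in range(len(block_ids)):
            for j in range(i + 1, len(block_ids)):
                ld_pairs.append((block_ids[i], block_ids[j], blocks.r2_within))

    meta_exp = TraitMeta("exposure_sim", "simulated taxon abundance", "exposure",
                         "continuous", truth.n_exp)
    meta_med = TraitMeta("mediator_sim", "simulated serum metabolite", "mediator",
                         "continuous", truth.n_med)
    n_case = int(round(truth.case_fraction * truth.n_out))
    meta_out = TraitMeta("outcome_sim", "simulated binary outcome", "outcome",
                         "binary", truth.n_out, n_case=n_case,
                         n_control=truth.n_out - n_case)
    return (
        SummaryStatsTable(meta_exp, pd.DataFrame(rows_exp)),
        SummaryStatsTable(meta_med, pd.DataFrame(rows_med)),
        SummaryStatsTable(meta_out, pd.DataFrame(rows_out)),
        LDInfo.from_pairs(ld_pairs),
        truth,
    )


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

_BUNDLE_FILES = ("exposure.tsv", "mediator.tsv", "outcome.tsv", "ld.tsv", "truth.json")


def write_fixture_bundle(
    directory: str | Path,
    truth: TripletTruth,
    tables: tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable],
    ld: LDInfo,
) -> dict:
    """Write the triplet as TSVs plus truth and a manifest with hashes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    exposure, mediator, outcome = tables
    exposure.to_tsv(directory / "exposure.tsv")
    mediator.to_tsv(directory / "mediator.tsv")
    outcome.to_tsv(directory / "outcome.tsv")
    ld.to_tsv(directory / "ld.tsv")
    truth_dict = dataclasses.asdict(truth)
    truth_dict["beta_total"] = truth.beta_total
    (directory / "truth.json").write_text(json.dumps(truth_dict, indent=1, sort_keys=True))

    manifest = {"seed": truth.seed, "files": {}}
    for name in _BUNDLE_FILES:
        digest = hashlib.sha256((directory / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_fixture_bundle(
    directory: str | Path,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable, LDInfo, dict]:
    """Load a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    truth = json.loads((directory / "truth.json").read_text())
    n_case = int(round(truth["case_fraction"] * truth["n_out"]))
    meta_exp = TraitMeta("exposure_sim", "simulated taxon abundance", "exposure",
                         "continuous", truth["n_exp"])
    meta_med = TraitMeta("mediator_sim", "simulated serum metabolite", "mediator",
                         "continuous", truth["n_med"])
    meta_out = TraitMeta("outcome_sim", "simulated binary outcome", "outcome",
                         "binary", truth["n_out"], n_case=n_case,
                         n_control=truth["n_out"] - n_case)
    return (
        read_sumstats(directory / "exposure.tsv", meta_exp),
        read_sumstats(directory / "mediator.tsv", meta_med),
        read_sumstats(directory / "outcome.tsv", meta_out),
        LDInfo.read_tsv(directory / "ld.tsv"),
        truth,
    )
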