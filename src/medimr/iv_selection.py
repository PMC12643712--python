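"""Instrument selection: p-value screen, greedy LD clumping, strength stats.

Instruments are genome-wide candidates passing a significance threshold
(default P < 1e-5), pruned to approximate linkage equilibrium by greedy
clumping (default r² < 0.001 within 500 kb), quantified by the variance
explained (PVE) and F-statistic, and filtered at F > 10. Known
confounder-associated variants can be excluded by id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats import ConfigError, InputError, SummaryStatsTable

logger = logging.getLogger("medimr")

__all__ = [
    "LDInfo",
    "InstrumentSet",
    "filter_pvalue",
    "ld_clump",
    "instrument_strength",
    "add_instrument_strength",
    "exclude_confounders",
    "select_instruments",
]


@dataclass
class LDInfo:
    """Sparse pairwise LD (r²) lookup. Absent pairs mean r² = 0."""

    r2: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.r2.get(self._key(a, b), 0.0)

    def set(self, a: str, b: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise InputError(f"r2 must be in [0,1], got {value} for ({a},{b})")
        self.r2[self._key(a, b)] = value

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "LDInfo":
        ld = cls()
        for a, b, r2 in pairs:
            ld.set(a, b, float(r2))
        return ld

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDInfo":
        """Read a 3-column (id_a, id_b, r2) tab-separated file."""
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns[:3])
        return cls.from_pairs(df[cols].itertuples(index=False, name=None))

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted((a, b, v) for (a, b), v in self.r2.items())
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentSet:
    """Selected instruments for one trait, with strength statistics.

    ``records`` carries the summary-statistics columns plus ``pve``,
    ``f_stat`` and ``weak``; ``provenance`` stores the thresholds used.
    """

    trait_id: str
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def as_table(self, meta) -> SummaryStatsTable:
        from .sumstats import COLUMNS

        return SummaryStatsTable(meta, self.records[COLUMNS].copy())


def filter_pvalue(table: SummaryStatsTable, threshold: float) -> SummaryStatsTable:
    """Subset to records with p-value strictly below ``threshold``,
    preserving input order."""
    return table.subset(table.records["pvalue"] < threshold)


def ld_clump(
    candidates: SummaryStatsTable,
    ld: LDInfo,
    r2_max: float = 0.001,
    window_kb: float = 500.0,
) -> SummaryStatsTable:
    """Greedy LD clumping.

    Candidates are ranked by ascending p-value (variant_id breaks ties);
    the best remaining variant is taken as an index and every remaining
    variant on the same chromosome within ``window_kb`` whose r² with the
    index is ≥ ``r2_max`` is discarded. Cross-chromosome pairs are never
    clumped. Output order follows the selection (p-then-id) ranking, so
    the result is independent of input record order.
    """
    df = candidates.records
    if df["position"].isna().any() or df["chromosome"].isna().any():
        bad = df.loc[df["position"].isna() | df["chromosome"].isna(), "variant_id"]
        raise InputError(f"candidates missing positions: {list(bad)}")
    ranked = df.sort_values(["pvalue", "variant_id"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000.0

    retained_ids: list[str] = []
    alive = np.ones(len(ranked), dtype=bool)
    chrom = ranked["chromosome"].to_numpy()
    pos = ranked["position"].to_numpy(float)
    vid = ranked["variant_id"].to_numpy()
    for i in range(len(ranked)):
        if not alive[i]:
            continue
        retained_ids.append(vid[i])
        for j in range(i + 1, len(ranked)):
            if not alive[j] or chrom[j] != chrom[i]:
                continue
            if abs(pos[j] - pos[i]) <= window_bp and ld.get(vid[i], vid[j]) >= r2_max:
                alive[j] = False
                logger.info("DROP variant=%s reason=clumped index=%s", vid[j], vid[i])
    keep = ranked[ranked["variant_id"].isin(retained_ids)]
    keep = keep.set_index("variant_id").loc[retained_ids].reset_index()
    return SummaryStatsTable(candidates.meta, keep)


def instrument_strength(
    beta: float,
    se: float,
    n: float,
    eaf: float | None = None,
    pve_formula: str = "standardized",
    f_formula: str = "pve",
) -> tuple[float, float, bool]:
    """Per-variant strength: (pve, f_stat, weak).

    PVE defaults to the standardized-trait form β²/(β² + n·se²), which
    needs no allele frequency; the EAF-based alternative 2β²·eaf·(1−eaf)
    is available. F defaults to pve·(n−2)/(1−pve); the Wald form (β/se)²
    agrees to first order and is selectable. ``weak`` means F ≤ 10.
    """
    if n is None or not np.isfinite(n):
        raise ConfigError("sample size n is required for instrument strength")
    if n < 3:
        raise ConfigError("instrument strength requires n >= 3")
    if se <= 0:
        raise InputError("se must be positive")
    if pve_formula == "standardized":
        pve = beta**2 / (beta**2 + n * se**2)
    elif pve_formula == "eaf":
        if eaf is None or not np.isfinite(eaf):
            raise ConfigError("pve_formula='eaf' requires an effect-allele frequency")
        pve = min(2.0 * beta**2 * eaf * (1.0 - eaf), 1.0 - 1e-12)
    else:
        raise ConfigError(f"unknown pve_formula {pve_formula!r}")
    if f_formula == "pve":
        f_stat = pve * (n - 2.0) / (1.0 - pve)
    elif f_formula == "wald":
        f_stat = (beta / se) ** 2
    else:
        raise ConfigError(f"unknown f_formula {f_formula!r}")
    return float(pve), float(f_stat), bool(f_stat <= 10.0)


def add_instrument_strength(
    table: SummaryStatsTable,
    n: float | None = None,
    pve_formula: str = "standardized",
    f_formula: str = "pve",
) -> pd.DataFrame:
    """Records with ``pve``, ``f_stat``, ``weak`` columns appended.

    Per-variant ``n`` takes precedence; otherwise ``n`` or the table's
    ``meta.sample_size`` is used for every record.
    """
    df = table.records.copy()
    fallback = n if n is not None else table.meta.sample_size
    out = []
    for row in df.itertuples(index=False):
        n_i = row.n if np.isfinite(getattr(row, "n", np.nan) or np.nan) else fallback
        if n_i is None:
            raise ConfigError(
                f"trait {table.meta.trait_id}: no per-variant n and no sample_size in meta"
            )
        out.append(
            instrument_strength(
                row.beta, row.se, float(n_i), eaf=row.eaf, pve_formula=pve_formula,
                f_formula=f_formula,
            )
        )
    df[["pve", "f_stat", "weak"]] = pd.DataFrame(out, index=df.index)
    return df


def exclude_confounders(
    instruments: InstrumentSet,
    exclusions: Sequence[tuple[str, str]] | Mapping[str, str] = (),
) -> InstrumentSet:
    """Remove instruments listed as confounder-associated.

    ``exclusions`` maps variant_id -> confounder label (or is a sequence
    of such pairs). Removals are logged; ids absent from the set are
    silently ignored.
    """
    if isinstance(exclusions, Mapping):
        excl = dict(exclusions)
    else:
        excl = {vid: label for vid, label in exclusions}
    mask = instruments.records["variant_id"].isin(excl)
    for vid in instruments.records.loc[mask, "variant_id"]:
        logger.info("DROP variant=%s reason=confounder label=%s", vid, excl[vid])
    records = instruments.records[~mask].reset_index(drop=True)
    prov = dict(instruments.provenance, n_confounder_excluded=int(mask.sum()))
    return InstrumentSet(instruments.trait_id, records, prov)


def select_instruments(
    table: SummaryStatsTable,
    ld: LDInfo,
    p_threshold: float = 1e-5,
    clump_r2: float = 0.001,
    clump_kb: float = 500.0,
    f_min: float = 10.0,
    n: float | None = None,
    exclusions: Sequence[tuple[str, str]] | Mapping[str, str] = (),
    pve_formula: str = "standardized",
    f_formula: str = "pve",
) -> InstrumentSet:
    """Full selection cascade: p-screen → clump → strength filter → exclusions."""
    sig = filter_pvalue(table, p_threshold)
    clumped = ld_clump(sig, ld, r2_max=clump_r2, window_kb=clump_kb)
    df = add_instrument_strength(clumped, n=n, pve_formula=pve_formula, f_formula=f_formula)
    weak = df["f_stat"] <= f_min
    for vid in df.loc[weak, "variant_id"]:
        logger.info("DROP variant=%s reason=weak_instrument f_min=%g", vid, f_min)
    df = df[~weak].reset_index(drop=True)
    provenance = {
        "p_threshold": p_threshold,
        "clump_r2": clump_r2,
        "clump_kb": clump_kb,
        "f_min": f_min,
        "pve_formula": pve_formula,
        "f_formula": f_formula,
    }
    selected = InstrumentSet(table.meta.trait_id, df, provenance)
    return exclude_confounders(selected, exclusions)
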