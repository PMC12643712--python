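"""GWAS summary-statistics containers, I/O, and allele harmonization.

A summary-statistics table holds one trait's per-variant association
records (rsID, alleles, effect size, standard error, p-value) together
with trait metadata. Binary traits carry effects on the log-odds scale.

Harmonization aligns an exposure table and an outcome table so that both
effect sizes are expressed per copy of the same effect allele — the
precondition for every two-sample MR estimator downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("medimr")

__all__ = [
    "TraitMeta",
    "SummaryStatsTable",
    "HarmonizedSet",
    "SumstatsError",
    "ConfigError",
    "InputError",
    "read_sumstats",
    "harmonize",
    "COLUMNS",
]

#: canonical column order of a summary-statistics record table
COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Base class for summary-statistics validation failures."""


class ConfigError(SumstatsError):
    """A configuration problem (e.g. a missing mandatory column)."""


class InputError(SumstatsError):
    """An input-data problem (e.g. a duplicated variant id)."""


@dataclass(frozen=True)
class TraitMeta:
    """Metadata for one GWAS trait.

    ``role`` is one of ``exposure``, ``mediator``, ``outcome``;
    ``trait_type`` is ``continuous`` or ``binary``. Binary traits are
    expected to report effects on the log-odds scale, with case/control
    counts in ``n_case``/``n_control``.
    """

    trait_id: str
    label: str = ""
    role: str = "exposure"
    trait_type: str = "continuous"
    sample_size: int | None = None
    n_case: int | None = None
    n_control: int | None = None

    def __post_init__(self) -> None:
        if not self.trait_id:
            raise ConfigError("trait_id must be non-empty")
        if self.role not in ("exposure", "mediator", "outcome"):
            raise ConfigError(f"unknown trait role {self.role!r}")
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        if self.sample_size is not None and self.sample_size <= 0:
            raise ConfigError("sample_size must be positive")


@dataclass
class SummaryStatsTable:
    """One trait's validated per-variant association records."""

    meta: TraitMeta
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigError(f"records missing columns: {missing}")
        dup = self.records["variant_id"][self.records["variant_id"].duplicated()]
        if len(dup):
            raise InputError(f"duplicate variant_id: {dup.iloc[0]!r}")
        self.records = self.records[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, mask) -> "SummaryStatsTable":
        """A new table with the same meta and the masked records."""
        return SummaryStatsTable(self.meta, self.records[mask].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _validate_rows(df: pd.DataFrame, strict: bool, trait_id: str) -> pd.DataFrame:
    """Apply row-level invariants; drop (permissive) or raise (strict)."""
    problems = pd.Series("", index=df.index, dtype=object)

    se = pd.to_numeric(df["se"], errors="coerce")
    p = pd.to_numeric(df["pvalue"], errors="coerce")
    beta = pd.to_numeric(df["beta"], errors="coerce")

    # p == 0 is clamped, not rejected: downstream ranking needs finite order
    zero_p = p == 0
    if zero_p.any():
        tiny = np.nextafter(0.0, 1.0)
        p = p.mask(zero_p, tiny)
        logger.warning(
            "trait=%s clamped %d zero p-values to %.3e", trait_id, int(zero_p.sum()), tiny
        )

    problems[se.isna() | (se <= 0)] = "se must be > 0"
    problems[p.isna() | (p <= 0) | (p > 1)] = "pvalue must be in (0,1]"
    problems[beta.isna()] = "beta must be numeric"
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    problems[ea == oa] = "effect_allele equals other_allele"
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    problems[eaf.notna() & ((eaf < 0) | (eaf > 1))] = "eaf outside [0,1]"

    bad = problems != ""
    if bad.any():
        lines = [
            f"row {i}: {msg} (variant_id={df.at[i, 'variant_id']!r})"
            for i, msg in problems[bad].items()
        ]
        if strict:
            raise InputError("invalid rows:\n" + "\n".join(lines))
        for line in lines:
            logger.warning("trait=%s dropped %s reason=invalid_row", trait_id, line)

    out = df.loc[~bad].copy()
    out["se"] = se[~bad]
    out["pvalue"] = p[~bad]
    out["beta"] = beta[~bad]
    out["eaf"] = eaf[~bad]
    out["effect_allele"] = ea[~bad]
    out["other_allele"] = oa[~bad]
    return out


def read_sumstats(
    path: str | Path,
    meta: TraitMeta,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> SummaryStatsTable:
    """Read a tab- or comma-separated summary-statistics file.

    Parameters
    ----------
    path
        File with a header row. The separator is sniffed (tab or comma).
    meta
        Trait metadata to attach.
    column_map
        Mapping from semantic field name (see :data:`COLUMNS`) to the
        physical column name in the file. Fields named identically can
        be omitted. ``eaf`` and ``n`` are optional fields.
    strict
        If True, any invalid row aborts the read; otherwise invalid rows
        are dropped with a logged diagnostic.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    mandatory = [c for c in COLUMNS if c not in ("eaf", "n")]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory columns {missing}")
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan
    df = _validate_rows(df[COLUMNS], strict=strict, trait_id=meta.trait_id)
    return SummaryStatsTable(meta, df)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

#: columns of a harmonized pair table
PAIR_COLUMNS = [
    "variant_id",
    "beta_exp",
    "se_exp",
    "pvalue_exp",
    "beta_out",
    "se_out",
    "eaf_exp",
    "eaf_out",
    "palindromic",
    "action",
]


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome effect pairs for one trait pair.

    ``pairs`` holds only surviving instruments (action ``kept_as_is`` or
    ``outcome_flipped``); ``dropped`` records the discarded variants with
    their reason so that counts are conserved.
    """

    exposure_meta: TraitMeta
    outcome_meta: TraitMeta
    pairs: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PAIR_COLUMNS))

    @property
    def k(self) -> int:
        """Number of surviving instruments."""
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        p = self.pairs
        return (
            p["beta_exp"].to_numpy(float),
            p["se_exp"].to_numpy(float),
            p["beta_out"].to_numpy(float),
            p["se_out"].to_numpy(float),
        )

    def to_tsv(self, path: str | Path) -> None:
        cols = ["variant_id", "beta_exp", "se_exp", "pvalue_exp", "beta_out", "se_out", "action"]
        pd.concat([self.pairs, self.dropped], ignore_index=True)[cols].to_csv(
            path, sep="\t", index=False
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"G", "C"})


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele.

    For each variant shared by both tables: matching alleles are kept as
    is; swapped alleles flip the outcome beta sign (and mirror its EAF);
    complementary alleles are strand-flipped first and then the same rule
    applies. Palindromic variants (A/T or G/C) are resolved by allele
    frequency — and dropped whenever either EAF lies within
    ``0.5 ± palindrome_eaf_window`` or is missing, since strand cannot be
    determined. Variants absent from either table are counted as
    ``dropped_missing``.
    """
    w = float(palindrome_eaf_window)
    exp = exposure.records.set_index("variant_id")
    out = outcome.records.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise InputError(
            f"no shared variants between {exposure.meta.trait_id} and {outcome.meta.trait_id}"
        )

    rows = []
    for vid in shared:
        e = exp.loc[vid]
        o = out.loc[vid]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        pal = _is_palindromic(ea_e, oa_e)
        beta_out, eaf_out = float(o["beta"]), o["eaf"]

        if pal:
            eaf_e, eaf_o = e["eaf"], o["eaf"]
            if pd.isna(eaf_e) or pd.isna(eaf_o) or abs(eaf_e - 0.5) <= w or abs(eaf_o - 0.5) <= w:
                action = "dropped_palindromic"
            elif (eaf_e - 0.5) * (eaf_o - 0.5) > 0:
                action = "kept_as_is"
            else:
                action = "outcome_flipped"
        elif (ea_o, oa_o) == (ea_e, oa_e):
            action = "kept_as_is"
        elif (ea_o, oa_o) == (oa_e, ea_e):
            action = "outcome_flipped"
        elif (_complement(ea_o), _complement(oa_o)) == (ea_e, oa_e):
            action = "kept_as_is"
        elif (_complement(ea_o), _complement(oa_o)) == (oa_e, ea_e):
            action = "outcome_flipped"
        else:
            action = "dropped_incompatible"

        if action == "outcome_flipped":
            beta_out = -beta_out
            if pd.notna(eaf_out):
                eaf_out = 1.0 - eaf_out
        rows.append(
            {
                "variant_id": vid,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "pvalue_exp": float(e["pvalue"]),
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "eaf_exp": e["eaf"],
                "eaf_out": eaf_out,
                "palindromic": pal,
                "action": action,
            }
        )

    # variants private to one table
    for vid in exp.index.difference(out.index):
        rows.append({"variant_id": vid, "palindromic": False, "action": "dropped_missing"})

    table = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    kept = table[table["action"].isin(["kept_as_is", "outcome_flipped"])].reset_index(drop=True)
    dropped = table[~table["action"].isin(["kept_as_is", "outcome_flipped"])].reset_index(
        drop=True
    )
    for _, r in dropped.iterrows():
        logger.info(
            "DROP variant=%s reason=%s pair=%s~%s",
            r["variant_id"],
            r["action"],
            exposure.meta.trait_id,
            outcome.meta.trait_id,
        )
    return HarmonizedSet(exposure.meta, outcome.meta, kept, dropped)
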