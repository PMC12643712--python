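"""Metabolite-set over-representation analysis against GMT libraries.

Each pathway is tested with the hypergeometric upper tail
P(X ≥ hits) where the population is the library's full metabolite
universe, successes are the pathway members and draws are the query
metabolites present in that universe; p-values are adjusted with the
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import InputError

logger = logging.getLogger("medimr")

__all__ = [
    "PathwayLibrary",
    "EnrichmentRecord",
    "load_gmt",
    "ora",
    "bh_fdr",
    "enrichment_network",
]


@dataclass(frozen=True)
class EnrichmentRecord:
    pathway_id: str
    name: str
    total: int
    hits: int
    hit_members: frozenset[str]
    pvalue: float
    fdr: float


@dataclass
class PathwayLibrary:
    """Named metabolite sets plus their union (the test background)."""

    pathways: list[tuple[str, str, frozenset[str]]]
    background: frozenset[str]

    def __len__(self) -> int:
        return len(self.pathways)


def _norm(name: str) -> str:
    return name.strip().casefold()


def load_gmt(path: str | Path) -> PathwayLibrary:
    """Parse a GMT file: one set per line, tab-separated
    (id, description, member, member, ...). Member ids are matched
    case-insensitively; duplicates within a line collapse."""
    pathways: list[tuple[str, str, frozenset[str]]] = []
    background: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            pid, desc = fields[0], fields[1]
            members = frozenset(_norm(m) for m in fields[2:] if m.strip())
            if not members:
                raise InputError(f"{path}:{lineno}: pathway {pid!r} has no members")
            pathways.append((pid, desc, members))
            background.update(members)
    if not pathways:
        logger.warning("GMT file %s is empty", path)
    return PathwayLibrary(pathways, frozenset(background))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must be in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(query: Iterable[str], library: PathwayLibrary) -> list[EnrichmentRecord]:
    """Over-representation analysis of a metabolite query set.

    Query members absent from the library background are dropped (with a
    logged count). Records are sorted by ascending p-value (pathway_id
    breaks ties).
    """
    q_raw = {_norm(m) for m in query}
    q = q_raw & library.background
    n_dropped = len(q_raw) - len(q)
    if n_dropped:
        logger.info("ora: %d query metabolites not in library background, dropped", n_dropped)
    if not q:
        raise InputError("no query metabolites map to the library background")

    m_pop = len(library.background)
    n_draw = len(q)
    raw = []
    for pid, name, members in library.pathways:
        hit_set = members & q
        hits = len(hit_set)
        total = len(members)
        # P(X >= hits); sf(hits-1) == 1 when hits == 0
        pval = float(stats.hypergeom.sf(hits - 1, m_pop, total, n_draw))
        raw.append((pid, name, total, hits, frozenset(hit_set), min(pval, 1.0)))

    fdrs = bh_fdr([r[5] for r in raw])
    records = [
        EnrichmentRecord(pid, name, total, hits, hit_set, pval, float(fdr))
        for (pid, name, total, hits, hit_set, pval), fdr in zip(raw, fdrs)
    ]
    records.sort(key=lambda r: (r.pvalue, r.pathway_id))
    return records


def enrichment_network(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Edges between pathways sharing at least one query hit.

    Edge weight is the Jaccard index of the two pathways' hit sets —
    plot-ready output for an external network renderer.
    """
    rows = []
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            shared = a.hit_members & b.hit_members
            if shared:
                union = a.hit_members | b.hit_members
                rows.append(
                    {
                        "source": a.pathway_id,
                        "target": b.pathway_id,
                        "weight": len(shared) / len(union),
                    }
                )
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway_id for r in records],
            "name": [r.name for r in records],
            "total_metabolites": [r.total for r in records],
            "metabolites_involved": [
                "; ".join(sorted(r.hit_members)) for r in records
            ],
            "hits": [r.hits for r in records],
            "pvalue": [r.pvalue for r in records],
            "fdr": [r.fdr for r in records],
        }
    )
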