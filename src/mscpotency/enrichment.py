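"""Hypergeometric over-representation analysis of metabolite panels.

Given a query set of consensus metabolites and user-supplied pathway sets
(GMT), each pathway is scored with the upper-tail hypergeometric probability
P(X >= k) of drawing k or more pathway members in a query of size n from a
background universe of size N containing K pathway members, followed by
Benjamini-Hochberg correction across pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import PathwayDB, ValidationError, logger


@dataclass
class EnrichmentResult:
    """One pathway's overlap statistics."""

    pathway: str
    K: int  # pathway size in the background
    n: int  # mapped query size
    k: int  # overlap
    N: int  # background size
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValidationError("overlap k outside [0, min(K, n)]")
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValidationError("p and q must lie in [0, 1]")


def map_query(query: Iterable[str], db: PathwayDB) -> tuple[set[str], list[str]]:
    """Intersect the query with the background; report unmapped ids verbatim."""
    mapped: set[str] = set()
    unmapped: list[str] = []
    for m in query:
        if m in db.background:
            mapped.add(m)
        else:
            unmapped.append(m)
    if unmapped:
        logger.info("%d of %d query metabolites mapped to the background",
                    len(mapped), len(mapped) + len(unmapped))
    return mapped, unmapped


def apply_id_mapping(query: Iterable[str], mapping: Mapping[str, str]) -> list[str]:
    """Translate query ids (e.g. lipid species -> class-level ids) before ORA."""
    out: list[str] = []
    for m in query:
        t = mapping.get(m, m)
        if t not in out:
            out.append(t)
    return out


def ora(mapped_query: Iterable[str], db: PathwayDB) -> list[EnrichmentResult]:
    """Over-representation analysis; results sorted by p ascending."""
    query = set(mapped_query)
    if not query:
        raise ValidationError("mapped query is empty")
    stray = query - db.background
    if stray:
        raise ValidationError(
            f"query ids outside the background: {sorted(stray)[:3]} — run map_query first"
        )
    N = len(db.background)
    n = len(query)
    rows = []
    for name, members in db.sets.items():
        mem = set(members)
        K = len(mem)
        k = len(query & mem)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, K, k, min(1.0, max(0.0, p))))
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(pathway=name, K=K, n=n, k=k, N=N, p=p, q=float(q))
        for (name, K, k, p), q in zip(rows, qvals)
    ]
    return sorted(results, key=lambda r: (r.p, r.pathway))


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """TSV-ready table with columns pathway, K, n, k, N, p, q."""
    return pd.DataFrame(
        [(r.pathway, r.K, r.n, r.k, r.N, r.p, r.q) for r in results],
        columns=["pathway", "K", "n", "k", "N", "p", "q"],
    )
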