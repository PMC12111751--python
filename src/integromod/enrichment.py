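"""Hypergeometric over-representation analysis (ORA) with BH FDR.

Module genes are tested against arbitrary gene-set collections (GO-like,
disease-ontology-like, drug-target) read from GMT.  The p-value per set
is the upper-tail hypergeometric probability of the observed overlap;
Benjamini-Hochberg adjustment runs across all tested sets.  The default
universe is the tested gene space (genes carrying node weights), not
the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float
    overlap_genes: list[str]


def hypergeom_upper(overlap: int, set_size: int, query_size: int,
                    universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, query_size)."""
    if not (0 <= overlap <= min(set_size, query_size)
            and set_size <= universe_size and query_size <= universe_size):
        raise ValueError("inconsistent hypergeometric counts")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def ora(query_genes: Iterable[str], collection: Mapping[str, Sequence[str]],
        universe: Iterable[str], alpha_mode: str = "fdr_q",
        threshold: float = 0.1) -> list[EnrichmentResult]:
    """Over-representation of the query against every set in the collection.

    Sets are intersected with the universe before testing; sets empty
    after intersection are skipped.  Results are sorted by ascending p
    and filtered by ``alpha_mode``: ``fdr_q`` keeps q < threshold (the
    GO-style rule), ``raw_p`` keeps p < threshold (disease/drug-target
    style), ``none`` keeps everything.
    """
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in query_genes}
    if not universe or not query:
        raise ValueError("universe and query must be non-empty")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    if alpha_mode not in ("fdr_q", "raw_p", "none"):
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")

    rows = []
    for name in collection:
        genes = {g.upper() for g in collection[name]} & universe
        if not genes:
            continue
        hit = sorted(genes & query)
        p = hypergeom_upper(len(hit), len(genes), len(query), len(universe))
        rows.append((name, hit, len(genes), p))
    qvals = bh_adjust([r[3] for r in rows])
    results = [EnrichmentResult(set_name=name, overlap=len(hit), set_size=ns,
                                query_size=len(query), universe_size=len(universe),
                                p=p, q=q, overlap_genes=hit)
               for (name, hit, ns, p), q in zip(rows, qvals)]
    results.sort(key=lambda r: (r.p, r.set_name))
    if alpha_mode == "fdr_q":
        results = [r for r in results if r.q < threshold]
    elif alpha_mode == "raw_p":
        results = [r for r in results if r.p < threshold]
    return results
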