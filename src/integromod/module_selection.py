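"""Ranking, merging and scale-free selection of normalised modules.

Modules are ranked by permutation-normalised score; the union of the
top n modules is reconstructed on the PPI and the scale-freeness of the
merged subnetwork is measured as the coefficient of determination (R^2)
of the ordinary least-squares fit of log degree frequency on log
degree, log(p_k) = -gamma log(k) + c.  The final subnetwork takes the
top fraction (10 % by default) of ranked modules; the achieved R^2 is
reported as a diagnostic, not enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Module
from .module_search import rank_modules

MIN_DISTINCT_DEGREES = 3


@dataclass
class ScaleFreeProfile:
    """Scale-free diagnostics of the merged top-``n_top`` subnetwork."""

    n_top: int
    genes: int
    edges: int
    r2: float | None
    gamma_hat: float | None


def merge_top_modules(modules: list[Module], n_top: int, ppi: nx.Graph) -> nx.Graph:
    """Union of the top ``n_top`` modules' genes with PPI-induced edges.

    ``modules`` must already be ranked; the node set is the gene union
    and the edge set every PPI edge internal to it.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_top > len(modules):
        raise ValueError(f"n_top={n_top} exceeds module count {len(modules)}")
    genes = set()
    for m in modules[:n_top]:
        genes.update(m.genes)
    sub = nx.Graph()
    sub.add_nodes_from(sorted(genes))
    sub.add_edges_from(e for e in ppi.subgraph(genes).edges())
    return sub


def degree_histogram(graph: nx.Graph) -> dict[int, int]:
    """Degree -> node count, restricted to degrees k >= 1."""
    hist: dict[int, int] = {}
    for _, k in graph.degree():
        if k >= 1:
            hist[k] = hist.get(k, 0) + 1
    return hist


def scale_free_r2(hist: Mapping[int, int], min_distinct: int = MIN_DISTINCT_DEGREES
                  ) -> tuple[float | None, float | None]:
    """R^2 and gamma of the log-log degree-distribution fit.

    p_k = count_k / total over degrees with nonzero count; OLS of
    log(p_k) on log(k); gamma_hat = -slope.  Returns (None, None) when
    fewer than ``min_distinct`` distinct degrees are present (any
    two-point fit is trivially R^2 = 1).
    """
    ks = sorted(k for k, c in hist.items() if c > 0 and k >= 1)
    if len(ks) < min_distinct:
        return None, None
    total = sum(hist[k] for k in ks)
    logk = np.log([float(k) for k in ks])
    logp = np.log([hist[k] / total for k in ks])
    fit = stats.linregress(logk, logp)
    return float(fit.rvalue**2), float(-fit.slope)


def selection_profile(modules: list[Module], ppi: nx.Graph, max_n: int | None = None
                      ) -> list[ScaleFreeProfile]:
    """Scale-free profile over n_top = 1 .. max_n merged top modules."""
    ranked = rank_modules(modules)
    max_n = len(ranked) if max_n is None else min(max_n, len(ranked))
    rows = []
    genes: set[str] = set()
    for n in range(1, max_n + 1):
        genes.update(ranked[n - 1].genes)
        sub = ppi.subgraph(genes)
        r2, gamma = scale_free_r2(degree_histogram(sub))
        rows.append(ScaleFreeProfile(n_top=n, genes=len(genes),
                                     edges=sub.number_of_edges(), r2=r2,
                                     gamma_hat=gamma))
    return rows


def profile_frame(profile: Sequence[ScaleFreeProfile]) -> pd.DataFrame:
    return pd.DataFrame([{"N_TOP": p.n_top, "GENES": p.genes, "EDGES": p.edges,
                          "R2": np.nan if p.r2 is None else p.r2,
                          "GAMMA": np.nan if p.gamma_hat is None else p.gamma_hat}
                         for p in profile])


def select_final(modules: list[Module], ppi: nx.Graph, fraction: float = 0.10
                 ) -> tuple[list[Module], nx.Graph, float | None]:
    """Select the top ``ceil(fraction * n)`` ranked modules.

    Returns the selected modules, the merged PPI-induced subnetwork and
    the median R^2 over the profile rows of the selected range (None if
    no row had a defined fit).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if not modules:
        raise ValueError("no modules to select from")
    ranked = rank_modules(modules)
    n_sel = math.ceil(fraction * len(ranked))
    selected = ranked[:n_sel]
    merged = merge_top_modules(ranked, n_sel, ppi)
    profile = selection_profile(selected, ppi, max_n=n_sel)
    r2s = [p.r2 for p in profile if p.r2 is not None]
    median_r2 = float(np.median(r2s)) if r2s else None
    return selected, merged, median_r2
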