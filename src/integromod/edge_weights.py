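"""Differential co-expression edge weights on the PPI network.

For each interaction whose endpoints are both measured, Pearson
correlation is computed separately in cases and controls and the edge
weight is the absolute Fisher-z difference

    z_edge = |atanh(r_case) - atanh(r_control)| / sqrt(1/(n1-3) + 1/(n2-3)),

the standard normal test statistic for equality of two correlations.
Edges with z_edge > 1.96 are flagged significant at the nominal level.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import EDGE_WEIGHT_COLUMNS

logger = logging.getLogger("integromod")

SIGNIFICANCE_Z = 1.96
_R_CLAMP = 0.999999


def pearson_by_group(expr: pd.DataFrame, samples: pd.DataFrame,
                     pair: tuple[str, str]) -> tuple[float, float]:
    """Pearson r of a gene pair in cases and controls separately.

    A gene constant within a group yields r = 0 for that group (with a
    warning) rather than dropping the edge.
    """
    a, b = pair
    for g in (a, b):
        if g not in expr.index:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    r = {}
    for group in ("case", "control"):
        cols = samples.loc[samples["GROUP"] == group, "SAMPLE"].tolist()
        if len(cols) < 4:
            raise ValueError(f"need >= 4 {group} samples, got {len(cols)}")
        x = expr.loc[a, cols].to_numpy(float)
        y = expr.loc[b, cols].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("constant expression for edge (%s, %s) in %s group; r set to 0",
                           a, b, group)
            r[group] = 0.0
        else:
            r[group] = float(np.corrcoef(x, y)[0, 1])
    return r["case"], r["control"]


def fisher_z_diff(r1: float, n1: int, r2: float, n2: int) -> float:
    """Absolute Fisher-transformed correlation difference, z-scaled.

    z = |atanh(r1) - atanh(r2)| / sqrt(1/(n1-3) + 1/(n2-3)); symmetric
    in its two arguments. Correlations are clamped to +/-0.999999.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each group needs n > 3")
    z1 = np.arctanh(np.clip(r1, -_R_CLAMP, _R_CLAMP))
    z2 = np.arctanh(np.clip(r2, -_R_CLAMP, _R_CLAMP))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(abs(z1 - z2) / se)


def build_edge_weights(expr: pd.DataFrame, samples: pd.DataFrame,
                       ppi: nx.Graph) -> pd.DataFrame:
    """Edge-weight table over all PPI edges with both endpoints measured.

    Correlations for all edges are computed from the per-group
    standardised expression matrix in one pass; the result is sorted by
    (GENE_A, GENE_B) and independent of sample column order and edge
    input order.
    """
    measured = set(expr.index)
    edges = sorted(tuple(sorted(e)) for e in ppi.edges()
                   if e[0] in measured and e[1] in measured)
    if not edges:
        raise ValueError("no PPI edge has both endpoints in the expression matrix")

    genes = sorted({g for e in edges for g in e})
    gidx = {g: i for i, g in enumerate(genes)}
    r_by_group = {}
    n_by_group = {}
    for group in ("case", "control"):
        cols = samples.loc[samples["GROUP"] == group, "SAMPLE"].tolist()
        if len(cols) < 4:
            raise ValueError(f"need >= 4 {group} samples, got {len(cols)}")
        n_by_group[group] = len(cols)
        x = expr.loc[genes, cols].to_numpy(float)
        sd = x.std(axis=1)
        const = sd == 0
        if const.any():
            logger.warning("%d genes constant in %s group; their correlations set to 0",
                           int(const.sum()), group)
        xc = x - x.mean(axis=1, keepdims=True)
        denom = np.where(const, 1.0, sd * len(cols))
        xs = xc / denom[:, None]
        corr = (xs @ xs.T) * len(cols)  # == corrcoef, constant genes give 0
        corr[const, :] = 0.0
        corr[:, const] = 0.0
        r_by_group[group] = corr

    rows = []
    for a, b in edges:
        rc = float(np.clip(r_by_group["case"][gidx[a], gidx[b]], -1, 1))
        rk = float(np.clip(r_by_group["control"][gidx[a], gidx[b]], -1, 1))
        z = fisher_z_diff(rc, n_by_group["case"], rk, n_by_group["control"])
        rows.append({"GENE_A": a, "GENE_B": b, "R_CASE": rc, "R_CONTROL": rk,
                     "Z_EDGE": z, "SIGNIFICANT": z > SIGNIFICANCE_Z})
    return pd.DataFrame(rows, columns=EDGE_WEIGHT_COLUMNS)


def edge_weight_map(table: pd.DataFrame, significant_only: bool = False
                    ) -> dict[tuple[str, str], float]:
    """Mapping from canonical edge to z_edge, optionally filtered to z > 1.96."""
    sub = table[table["SIGNIFICANT"]] if significant_only else table
    return {tuple(sorted((a, b))): float(z)
            for a, b, z in zip(sub["GENE_A"], sub["GENE_B"], sub["Z_EDGE"])}
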