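"""Synthetic multi-omics data with planted, parameterised signal.

Every pipeline stage is testable without external downloads: this module
generates scale-free PPI networks, GWAS gene-level p-values with a
planted low-p module, 450K-like case/control methylation beta matrices
with a planted delta-beta shift, case/control expression with elevated
co-expression on planted edges, and two-sample MR instrument tables with
a known causal effect.  Every generator is a pure function of
(parameters, seed); the planted truth is recorded in
:class:`SyntheticTruth` for recovery scoring.

Seeds: one global seed is supplied and per-stage streams are derived
from it via a CRC32 hash of the stage name, so any stage can be
regenerated independently of the others.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats

logger = logging.getLogger("integromod")


def derive_seed(seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from the global seed (stable, < 2**31)."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic bundle."""

    planted_genes: list[str]
    planted_edges: list[tuple[str, str]]
    gwas_effect: float
    meth_delta_beta: float
    rho_case: float
    rho_control: float
    mr_theta: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_edges"] = [list(e) for e in self.planted_edges]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_edges"] = [tuple(e) for e in d["planted_edges"]]
        return cls(**d)


# PPI topology ----------------------------------------------------------------

def generate_ppi(n_genes: int, m_attach: int = 3, seed: int = 0) -> nx.Graph:
    """Preferential-attachment (Barabási–Albert) PPI with ``n_genes`` nodes.

    Produces an approximately scale-free degree distribution, matching
    the power-law topology expected of real interactomes.  Nodes are
    named ``G0001``, ``G0002``, ... in generation order.
    """
    if not (n_genes > m_attach >= 1):
        raise ValueError(f"need n_genes > m_attach >= 1, got {n_genes}, {m_attach}")
    g = nx.barabasi_albert_graph(n_genes, m_attach, seed=int(seed))
    width = max(4, len(str(n_genes)))
    mapping = {i: f"G{i + 1:0{width}d}" for i in g.nodes()}
    return nx.relabel_nodes(g, mapping)


def plant_module(ppi: nx.Graph, size: int, seed: int = 0) -> list[str]:
    """Choose a connected gene set by seeded random BFS from a random start.

    Returns the planted gene list sorted; the induced subgraph is
    connected by construction.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    components = sorted(nx.connected_components(ppi), key=len, reverse=True)
    if not components or len(components[0]) < size:
        raise ValueError(f"no connected component of size >= {size}")
    rng = np.random.default_rng(derive_seed(seed, "plant_module"))
    comp = sorted(components[0])
    start = comp[rng.integers(len(comp))]
    chosen = [start]
    frontier = sorted(ppi.neighbors(start))
    seen = {start}
    while len(chosen) < size:
        # random BFS: pick uniformly among nodes adjacent to the module
        frontier = [n for n in frontier if n not in seen]
        if not frontier:
            raise ValueError("ran out of frontier; component smaller than size")
        nxt = frontier[rng.integers(len(frontier))]
        chosen.append(nxt)
        seen.add(nxt)
        frontier = sorted(set(frontier) | set(ppi.neighbors(nxt)))
    return sorted(chosen)


def planted_edges_of(ppi: nx.Graph, planted: list[str]) -> list[tuple[str, str]]:
    """PPI edges internal to the planted gene set (canonically ordered)."""
    sub = ppi.subgraph(planted)
    return sorted(tuple(sorted(e)) for e in sub.edges())


# GWAS gene-level p-values ----------------------------------------------------

def simulate_gene_pvalues(genes: list[str], planted: list[str] | None = None,
                          effect: float = 3.0, seed: int = 0) -> dict[str, float]:
    """Gene p-values as the upper tail of simulated association z-scores.

    Background genes draw z ~ N(0, 1) (p uniform under the null);
    planted genes draw z ~ N(effect, 1).  p = 1 - Phi(z), clamped to
    [1e-300, 1 - 1e-16].
    """
    if effect < 0:
        raise ValueError("effect must be >= 0")
    planted_set = set(planted or [])
    rng = np.random.default_rng(derive_seed(seed, "gene_pvalues"))
    genes = list(genes)
    z = rng.standard_normal(len(genes))
    for i, g in enumerate(genes):
        if g in planted_set:
            z[i] += effect
    p = np.clip(stats.norm.sf(z), 1e-300, 1 - 1e-16)
    return dict(zip(genes, p.tolist()))


# Methylation -----------------------------------------------------------------

def default_gene_annotation(genes: list[str], gene_length: int = 20_000,
                            spacing: int = 100_000) -> pd.DataFrame:
    """Lay genes head-to-tail on one synthetic chromosome, alternating strand."""
    rows = []
    for i, g in enumerate(sorted(genes)):
        start = 1_000_000 + i * spacing
        rows.append({"GENE": g, "CHROM": "chr1", "START": start,
                     "END": start + gene_length - 1,
                     "STRAND": "+" if i % 2 == 0 else "-"})
    return pd.DataFrame(rows, columns=io_formats.GENE_ANNOT_COLUMNS)


def _beta_from_m(m: np.ndarray) -> np.ndarray:
    # inverse of M = log2(beta / (1 - beta))
    return 1.0 / (1.0 + np.exp2(-m))


def simulate_methylation(gene_annot: pd.DataFrame, planted: list[str] | None = None,
                         n_case: int = 13, n_control: int = 15,
                         probes_per_gene: int = 3, delta_beta: float = 0.2,
                         seed: int = 0, m_sd: float = 0.5,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Case/control beta matrix with a planted shift on planted genes' probes.

    Probes sit in the TSS1500 promoter window at 200, 700, 1200, ... bp
    upstream of the TSS (strand-aware).  Control M-values draw
    N(0, m_sd^2); beta = logistic2(M).  Case probes of planted genes
    shift M by the logit offset that moves beta from 0.5 to
    0.5 + delta_beta, so the planted mean beta difference is close to
    ``delta_beta`` at the centre of the beta scale.
    """
    if not (-0.5 < delta_beta < 0.5):
        raise ValueError("delta_beta must lie in (-0.5, 0.5)")
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    planted_set = set(planted or [])
    rng = np.random.default_rng(derive_seed(seed, "methylation"))

    probe_rows = []
    for _, g in gene_annot.iterrows():
        tss = g["START"] if g["STRAND"] == "+" else g["END"]
        for j in range(probes_per_gene):
            offset = 200 + 500 * j  # upstream of TSS on the 5' side
            pos = tss - offset if g["STRAND"] == "+" else tss + offset
            probe_rows.append({"PROBE": f"cg_{g['GENE']}_{j}", "CHROM": g["CHROM"],
                               "POS": max(1, int(pos)), "GENE": g["GENE"],
                               "STRAND": g["STRAND"]})
    probe_annot = pd.DataFrame(probe_rows, columns=io_formats.PROBE_ANNOT_COLUMNS)

    samples = ([f"CASE{i + 1:03d}" for i in range(n_case)]
               + [f"CTRL{i + 1:03d}" for i in range(n_control)])
    groups = ["case"] * n_case + ["control"] * n_control
    sheet = pd.DataFrame({"SAMPLE": samples, "GROUP": groups})

    n_probes = len(probe_annot)
    m = rng.normal(0.0, m_sd, size=(n_probes, n_case + n_control))
    if delta_beta != 0 and planted_set:
        m_offset = np.log2((0.5 + delta_beta) / (0.5 - delta_beta))
        planted_rows = probe_annot["GENE"].isin(planted_set).to_numpy()
        m[np.ix_(planted_rows, np.arange(n_case))] += m_offset
    beta = _beta_from_m(m)
    beta_df = pd.DataFrame(beta, index=probe_annot["PROBE"].tolist(), columns=samples)
    return beta_df, probe_annot, sheet


# Expression ------------------------------------------------------------------

def _nearest_psd_corr(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped nearest-PSD repair, rescaled to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def simulate_expression(ppi: nx.Graph, planted_edges: list[tuple[str, str]] | None = None,
                        n_case: int = 50, n_control: int = 50,
                        rho_case: float = 0.8, rho_control: float = 0.0,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case/control expression with elevated correlation on planted edges.

    Per group the target correlation matrix has 1 on the diagonal,
    ``rho_group`` on planted edges and 0 elsewhere; it is repaired to
    PSD by eigenvalue clipping and samples are multivariate normal.
    """
    for rho in (rho_case, rho_control):
        if not (-1 < rho < 1):
            raise ValueError("|rho| must be < 1")
    genes = sorted(ppi.nodes())
    idx = {g: i for i, g in enumerate(genes)}
    planted_edges = [tuple(sorted(e)) for e in (planted_edges or [])]
    rng = np.random.default_rng(derive_seed(seed, "expression"))

    def group_sample(rho: float, n: int) -> np.ndarray:
        corr = np.eye(len(genes))
        for a, b in planted_edges:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
        fixed = _nearest_psd_corr(corr)
        worst = max((abs(fixed[idx[a], idx[b]] - rho) for a, b in planted_edges),
                    default=0.0)
        if worst > 0.1:
            logger.warning("PSD repair moved a planted correlation by %.3f", worst)
        chol = np.linalg.cholesky(fixed + 1e-12 * np.eye(len(genes)))
        return (chol @ rng.standard_normal((len(genes), n)))

    x_case = group_sample(rho_case, n_case)
    x_ctrl = group_sample(rho_control, n_control)
    samples = ([f"CASE{i + 1:03d}" for i in range(n_case)]
               + [f"CTRL{i + 1:03d}" for i in range(n_control)])
    sheet = pd.DataFrame({"SAMPLE": samples,
                          "GROUP": ["case"] * n_case + ["control"] * n_control})
    expr = pd.DataFrame(np.hstack([x_case, x_ctrl]), index=genes, columns=samples)
    return expr, sheet


# Mendelian randomization -----------------------------------------------------

def simulate_mr(n_snps: int = 50, theta: float = 0.3, pleiotropy_sd: float = 0.0,
                seed: int = 0) -> pd.DataFrame:
    """Two-sample MR instrument table with true causal effect ``theta``.

    beta_X ~ N(0.15, 0.05^2) clamped positive with se_X = 0.01;
    beta_Y = theta * beta_X + alpha + eps with alpha ~ N(0, pleiotropy_sd^2),
    eps ~ N(0, se_Y^2) and se_Y = 0.02.
    """
    if n_snps < 2:
        raise ValueError("n_snps must be >= 2")
    rng = np.random.default_rng(derive_seed(seed, "mr"))
    bx = np.clip(rng.normal(0.15, 0.05, n_snps), 1e-3, None)
    se_x = np.full(n_snps, 0.01)
    se_y = np.full(n_snps, 0.02)
    alpha = rng.normal(0.0, pleiotropy_sd, n_snps) if pleiotropy_sd > 0 else np.zeros(n_snps)
    by = theta * bx + alpha + rng.normal(0.0, se_y)
    return pd.DataFrame({"SNP": [f"rs{i + 1:05d}" for i in range(n_snps)],
                         "BETA_EXPOSURE": bx, "SE_EXPOSURE": se_x,
                         "BETA_OUTCOME": by, "SE_OUTCOME": se_y})


# Full bundle -----------------------------------------------------------------

@dataclass
class BundleConfig:
    """Parameters of a full synthetic study bundle (the study conditions)."""

    n_genes: int = 300
    m_attach: int = 3
    planted_size: int = 8
    gwas_effect: float = 3.0
    meth_delta_beta: float = 0.2
    n_case_meth: int = 13
    n_control_meth: int = 15
    probes_per_gene: int = 3
    n_case_expr: int = 50
    n_control_expr: int = 50
    rho_case: float = 0.8
    rho_control: float = 0.0
    n_snps_mr: int = 50
    mr_theta: float = 0.3
    mr_pleiotropy_sd: float = 0.0
    seed: int = 0


def simulate_bundle(config: BundleConfig, outdir: str | Path) -> SyntheticTruth:
    """Generate and write the full synthetic dataset bundle.

    Writes PPI TSV, gene annotation, gene p-values, beta matrix, probe
    annotation, expression matrix, sample sheets, MR table and truth
    JSON under ``outdir``; returns the planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = config
    ppi = generate_ppi(c.n_genes, c.m_attach, seed=derive_seed(c.seed, "ppi"))
    planted = plant_module(ppi, c.planted_size, seed=c.seed)
    pe = planted_edges_of(ppi, planted)
    genes = sorted(ppi.nodes())

    io_formats.write_ppi(ppi, outdir / "ppi.tsv")
    annot = default_gene_annotation(genes)
    annot.to_csv(outdir / "gene_annotation.tsv", sep="\t", index=False)

    pvals = simulate_gene_pvalues(genes, planted, c.gwas_effect, seed=c.seed)
    pd.DataFrame({"GENE": genes, "P": [pvals[g] for g in genes]}).to_csv(
        outdir / "gene_pvalues.tsv", sep="\t", index=False, float_format="%.10g")

    beta, probe_annot, meth_sheet = simulate_methylation(
        annot, planted, c.n_case_meth, c.n_control_meth,
        c.probes_per_gene, c.meth_delta_beta, seed=c.seed)
    io_formats.write_matrix(beta, outdir / "methylation_beta.tsv")
    probe_annot.to_csv(outdir / "probe_annotation.tsv", sep="\t", index=False)
    meth_sheet.to_csv(outdir / "methylation_samples.tsv", sep="\t", index=False)

    expr, expr_sheet = simulate_expression(
        ppi, pe, c.n_case_expr, c.n_control_expr, c.rho_case, c.rho_control, seed=c.seed)
    io_formats.write_matrix(expr, outdir / "expression.tsv")
    expr_sheet.to_csv(outdir / "expression_samples.tsv", sep="\t", index=False)

    mr = simulate_mr(c.n_snps_mr, c.mr_theta, c.mr_pleiotropy_sd, seed=c.seed)
    mr.to_csv(outdir / "mr_instruments.tsv", sep="\t", index=False, float_format="%.10g")

    truth = SyntheticTruth(planted_genes=planted, planted_edges=pe,
                           gwas_effect=c.gwas_effect, meth_delta_beta=c.meth_delta_beta,
                           rho_case=c.rho_case, rho_control=c.rho_control,
                           mr_theta=c.mr_theta, seed=c.seed)
    truth.to_json(outdir / "truth.json")
    return truth
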