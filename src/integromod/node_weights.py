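"""Gene-level node weights fusing GWAS and differential-methylation evidence.

The GWAS arm converts gene-level association p-values to z-scores via
the inverse normal distribution, z = Phi^-1(1 - p), after excluding the
MHC region (chr6:25,000,000-33,500,000) whose extreme LD inflates
gene scores.  When only SNP-level statistics are available, a windowed
Šidák-corrected minimum-p aggregator maps SNPs to genes (35 kb upstream
/ 10 kb downstream, strand-aware); externally computed gene p-values
(e.g. from a dedicated gene-based test) are accepted directly.

The methylation arm runs a probe-level differential test on M-values
(Welch t by default), converts probe p-values to signed z-scores
(positive = hypermethylated in cases) and aggregates probes in the
TSS1500 promoter window per gene by Stouffer's method.

The two arms are fused per gene: a variance-matching scaling factor
s = sd(z_gwas) / sd(|z_meth|) over shared genes puts the methylation
magnitudes on the GWAS scale, and the fused node weight is the Stouffer
combination (z_gwas + s*|z_meth|) / sqrt(2).  The methylation sign is
kept as annotation for hypo/hyper reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GENE_SCORE_COLUMNS

logger = logging.getLogger("integromod")

MHC_REGION = ("6", 25_000_000, 33_500_000)


# GWAS arm --------------------------------------------------------------------

def gwas_z_from_p(p: float) -> float:
    """z = Phi^-1(1 - p); p clamped below at 1e-300."""
    if not (0 < p <= 1):
        raise ValueError(f"p must lie in (0, 1], got {p}")
    return float(stats.norm.isf(max(p, 1e-300)))


def snp_to_gene_minp(snps: pd.DataFrame, annot: pd.DataFrame,
                     up_bp: int = 35_000, down_bp: int = 10_000) -> dict[str, float]:
    """Šidák-corrected minimum SNP p per gene window (strand-aware).

    The window extends ``up_bp`` on the 5' side and ``down_bp`` on the
    3' side of the gene body (1-based inclusive).  With k SNPs in the
    window, gene p = 1 - (1 - min p)^k; genes with no SNPs are absent.
    """
    out: dict[str, float] = {}
    snps_by_chrom = {c: sub for c, sub in snps.groupby("CHROM")}
    for _, g in annot.iterrows():
        sub = snps_by_chrom.get(g["CHROM"])
        if sub is None:
            continue
        if g["STRAND"] == "+":
            lo, hi = g["START"] - up_bp, g["END"] + down_bp
        else:
            lo, hi = g["START"] - down_bp, g["END"] + up_bp
        in_win = sub[(sub["POS"] >= lo) & (sub["POS"] <= hi)]
        k = len(in_win)
        if k == 0:
            continue
        minp = float(in_win["P"].min())
        # Šidák correction for taking the best of k tests
        out[g["GENE"]] = float(-np.expm1(k * np.log1p(-minp)))
    return out


def _norm_chrom(c: str) -> str:
    return str(c).lower().removeprefix("chr")


def exclude_mhc(scores: pd.DataFrame, annot: pd.DataFrame,
                region: tuple[str, int, int] = MHC_REGION) -> pd.DataFrame:
    """Null out GWAS scores of genes overlapping the MHC region.

    Any overlap of the gene's [START, END] with the region counts; the
    methylation column is untouched.
    """
    chrom, lo, hi = region
    ann = annot.set_index("GENE")
    out = scores.copy()
    for i, row in out.iterrows():
        g = row["GENE"]
        if g not in ann.index:
            continue
        a = ann.loc[g]
        if _norm_chrom(a["CHROM"]) == _norm_chrom(chrom) and a["START"] <= hi and a["END"] >= lo:
            out.at[i, "P_GWAS"] = np.nan
            out.at[i, "Z_GWAS"] = np.nan
    return out


# Methylation arm -------------------------------------------------------------

@dataclass
class DiffMethResult:
    """Per-probe differential methylation on the M-value scale."""

    probe_id: str
    delta_m: float
    t_stat: float
    p: float
    z_signed: float


def m_values(beta: pd.DataFrame) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)), beta clamped to [1e-6, 1 - 1e-6]."""
    b = beta.clip(1e-6, 1 - 1e-6)
    return np.log2(b / (1 - b))


def diff_methylation(beta: pd.DataFrame, samples: pd.DataFrame,
                     pooled_variance: bool = False) -> list[DiffMethResult]:
    """Two-sample t-test per probe on M-values, case vs control.

    Welch's unequal-variance t by default; ``pooled_variance=True``
    switches to the classical pooled test.  The signed z is
    sign(delta_m) * Phi^-1(1 - p/2), positive for hypermethylation in
    cases.  Probes with zero variance in both groups get p = 1, z = 0.
    """
    cases = samples.loc[samples["GROUP"] == "case", "SAMPLE"].tolist()
    ctrls = samples.loc[samples["GROUP"] == "control", "SAMPLE"].tolist()
    if len(cases) < 2 or len(ctrls) < 2:
        raise ValueError("need >= 2 samples per group")
    m = m_values(beta)
    mc = m[cases].to_numpy()
    mk = m[ctrls].to_numpy()
    delta = mc.mean(axis=1) - mk.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(mc, mk, axis=1, equal_var=pooled_variance)
    results = []
    for probe, d, ti, pi in zip(beta.index, delta, t, p):
        if np.isnan(ti):  # zero variance in both groups
            ti, pi = 0.0, 1.0
        z = float(np.sign(d) * stats.norm.isf(max(pi, 1e-300) / 2)) if pi < 1 else 0.0
        results.append(DiffMethResult(probe_id=str(probe), delta_m=float(d),
                                      t_stat=float(ti), p=float(pi), z_signed=z))
    return results


def tss_region_probes(probe_annot: pd.DataFrame, gene_annot: pd.DataFrame,
                      window_bp: int = 1500) -> pd.DataFrame:
    """Probes inside the TSS1500 window of their annotated gene.

    For + strand genes the TSS is the annotation START and the window is
    [TSS - window_bp, TSS]; for - strand genes the TSS is END and the
    window is [TSS, TSS + window_bp] (upstream lies at higher
    coordinates).
    """
    ann = gene_annot.set_index("GENE")
    keep = []
    for i, row in probe_annot.iterrows():
        g = row["GENE"]
        if g not in ann.index:
            continue
        a = ann.loc[g]
        if a["STRAND"] == "+":
            tss = a["START"]
            ok = tss - window_bp <= row["POS"] <= tss
        else:
            tss = a["END"]
            ok = tss <= row["POS"] <= tss + window_bp
        if ok:
            keep.append(i)
    return probe_annot.loc[keep]


def stouffer_gene_score(probe_results: list[DiffMethResult],
                        tss_probes: pd.DataFrame) -> dict[str, float]:
    """Stouffer aggregation of signed probe z-scores per gene.

    z_gene = (sum z_i) / sqrt(n) over the n probes assigned to the
    gene's TSS region.  Genes with no contributing probes are absent.
    The result is independent of probe input order.
    """
    z_by_probe = {r.probe_id: r.z_signed for r in probe_results}
    sums: dict[str, list[float]] = {}
    for _, row in tss_probes.iterrows():
        z = z_by_probe.get(row["PROBE"])
        if z is None:
            continue
        sums.setdefault(row["GENE"], []).append(z)
    return {g: float(np.sum(zs) / np.sqrt(len(zs))) for g, zs in sorted(sums.items())}


# Fusion ----------------------------------------------------------------------

def combine_node_weights(z_gwas: dict[str, float], z_meth: dict[str, float],
                         signed_methylation: bool = False) -> pd.DataFrame:
    """Fuse GWAS and methylation z-scores into per-gene node weights.

    The scaling factor s = sd(z_gwas) / sd(|z_meth|) over genes shared
    by both arms matches the two variances; genes with both sources get
    node_weight = (z_gwas + s*|z_meth|) / sqrt(2), single-source genes
    carry their (scaled) single score.  ``signed_methylation=True``
    combines the signed methylation z instead of its magnitude.
    """
    if not z_gwas or not z_meth:
        raise ValueError("both score maps must be non-empty")
    meth_term = (lambda z: z) if signed_methylation else abs
    shared = sorted(set(z_gwas) & set(z_meth))
    if len(shared) >= 2:
        sd_g = float(np.std([z_gwas[g] for g in shared], ddof=1))
        sd_m = float(np.std([meth_term(z_meth[g]) for g in shared], ddof=1))
    else:
        sd_g, sd_m = 1.0, 1.0
        logger.warning("fewer than 2 shared genes; scaling factor fixed at 1")
    if sd_m == 0:
        raise ValueError("methylation z-scores have zero variance on shared genes")
    s = sd_g / sd_m if sd_g > 0 else 1.0
    rows = []
    for g in sorted(set(z_gwas) | set(z_meth)):
        zg = z_gwas.get(g)
        zm = z_meth.get(g)
        if zg is not None and zm is not None:
            w = (zg + s * meth_term(zm)) / np.sqrt(2)
        elif zg is not None:
            w = zg
        else:
            w = s * meth_term(zm)
        rows.append({"GENE": g, "P_GWAS": np.nan,
                     "Z_GWAS": np.nan if zg is None else zg,
                     "Z_METH": np.nan if zm is None else zm,
                     "NODE_WEIGHT": float(w)})
    return pd.DataFrame(rows, columns=GENE_SCORE_COLUMNS)


def gene_scores_from_pvalues(gene_p: dict[str, float]) -> dict[str, float]:
    """Vectorised p -> z conversion for a gene p-value map."""
    return {g: gwas_z_from_p(p) for g, p in gene_p.items()}


def build_gene_scores(gene_p: dict[str, float] | None,
                      z_meth: dict[str, float] | None,
                      annot: pd.DataFrame | None = None,
                      signed_methylation: bool = False) -> pd.DataFrame:
    """End-to-end node-weight table from gene p-values and/or methylation z.

    MHC exclusion (when annotation is supplied) is applied to the GWAS
    arm before the scaling factor is estimated, so MHC genes never
    influence the variance matching.
    """
    z_gwas = gene_scores_from_pvalues(gene_p) if gene_p else {}
    if z_gwas and annot is not None:
        tbl = pd.DataFrame({"GENE": list(z_gwas), "P_GWAS": [gene_p[g] for g in z_gwas],
                            "Z_GWAS": list(z_gwas.values()),
                            "Z_METH": np.nan, "NODE_WEIGHT": np.nan})
        tbl = exclude_mhc(tbl, annot)
        z_gwas = {g: z for g, z in zip(tbl["GENE"], tbl["Z_GWAS"]) if not np.isnan(z)}
    if z_gwas and z_meth:
        out = combine_node_weights(z_gwas, z_meth, signed_methylation)
    elif z_gwas:
        out = pd.DataFrame({"GENE": sorted(z_gwas),
                            "Z_GWAS": [z_gwas[g] for g in sorted(z_gwas)]})
        out["P_GWAS"] = np.nan
        out["Z_METH"] = np.nan
        out["NODE_WEIGHT"] = out["Z_GWAS"]
        out = out[GENE_SCORE_COLUMNS]
    elif z_meth:
        out = pd.DataFrame({"GENE": sorted(z_meth),
                            "Z_METH": [z_meth[g] for g in sorted(z_meth)]})
        out["P_GWAS"] = np.nan
        out["Z_GWAS"] = np.nan
        zm = out["Z_METH"] if signed_methylation else out["Z_METH"].abs()
        out["NODE_WEIGHT"] = zm
        out = out[GENE_SCORE_COLUMNS]
    else:
        raise ValueError("at least one evidence source required")
    if gene_p:
        out["P_GWAS"] = out["GENE"].map(lambda g: gene_p.get(g, np.nan))
        out.loc[out["Z_GWAS"].isna(), "P_GWAS"] = np.nan
    return out
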