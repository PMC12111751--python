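"""Readers and writers for the tabular formats the pipeline consumes.

All downstream modules work on the in-memory containers produced here:
:class:`networkx.Graph` for protein--protein interaction (PPI) networks,
:class:`pandas.DataFrame` for tabular data (SNPs, gene annotation, probe
annotation, sample sheets, omics matrices, edge-weight and gene-score
tables) and :class:`Module` dataclasses for search results.

Conventions
-----------
* Gene identifiers are uppercase symbols everywhere; cross-omics matching
  is exact-string (no alias resolution).
* Genomic coordinates are 1-based inclusive (Illumina 450K ``MAPINFO``
  convention).
* TSV is the canonical tabular dialect; matrices may be comma separated
  via ``sep=","``.
* Missing matrix values are encoded ``NA``; rows with more than 20 %
  missing are dropped, the rest are imputed by row median.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("integromod")

# Canonical column names ------------------------------------------------------

SNP_COLUMNS = ["SNP", "CHROM", "POS", "P"]
GENE_ANNOT_COLUMNS = ["GENE", "CHROM", "START", "END", "STRAND"]
PROBE_ANNOT_COLUMNS = ["PROBE", "CHROM", "POS", "GENE", "STRAND"]
SAMPLE_SHEET_COLUMNS = ["SAMPLE", "GROUP"]
GENE_SCORE_COLUMNS = ["GENE", "P_GWAS", "Z_GWAS", "Z_METH", "NODE_WEIGHT"]
EDGE_WEIGHT_COLUMNS = ["GENE_A", "GENE_B", "R_CASE", "R_CONTROL", "Z_EDGE", "SIGNIFICANT"]
MR_COLUMNS = ["SNP", "BETA_EXPOSURE", "SE_EXPOSURE", "BETA_OUTCOME", "SE_OUTCOME"]


class FormatError(ValueError):
    """Raised for malformed input files; message carries the line number."""


@dataclass
class Module:
    """A dense module: a seed gene plus the genes recruited around it.

    ``zm`` is the raw module score, ``zn`` the permutation-normalised
    score (``None`` until normalisation runs, ``math.nan`` if the
    permutation spread was degenerate).
    """

    id: str
    seed: str
    genes: list[str]
    zm: float
    zn: float | None = None
    mode: str = "node"
    degenerate: bool = False

    @property
    def size(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        zn = self.zn
        if isinstance(zn, float) and math.isnan(zn):
            zn = None  # strict JSON: degenerate zn serialises as null
        return {
            "id": self.id,
            "seed": self.seed,
            "genes": list(self.genes),
            "zm": self.zm,
            "zn": zn,
            "size": self.size,
            "mode": self.mode,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Module":
        return cls(
            id=d["id"],
            seed=d["seed"],
            genes=list(d["genes"]),
            zm=float(d["zm"]),
            zn=None if d.get("zn") is None else float(d["zn"]),
            mode=d.get("mode", "node"),
            degenerate=bool(d.get("degenerate", False)),
        )


# PPI networks ----------------------------------------------------------------

def build_ppi(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Build an undirected, deduplicated, self-loop-free PPI graph.

    Gene symbols are uppercased; an edge ``(a, b)`` is stored once
    regardless of orientation in the input.
    """
    g = nx.Graph()
    for a, b in edges:
        a, b = a.strip().upper(), b.strip().upper()
        if not a or not b or a == b:
            continue
        g.add_edge(a, b)
    return g


def read_ppi(path: str | Path, dialect: str = "plain", taxon: int = 9606,
             extra_edges: str | Path | None = None) -> nx.Graph:
    """Read a PPI network from a plain two-column TSV or a BioGRID tab3 file.

    ``biogrid_tab3`` keeps only rows where both organism columns equal
    ``taxon`` and the experimental-system-type column is ``physical``.
    ``extra_edges`` optionally unions a second plain edge list into the
    network (for merging a second interaction source).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    if dialect == "plain":
        edges.extend(_read_plain_edges(path))
    elif dialect == "biogrid_tab3":
        edges.extend(_read_biogrid_tab3(path, taxon))
    else:
        raise ValueError(f"unknown PPI dialect {dialect!r}")
    if extra_edges is not None:
        edges.extend(_read_plain_edges(Path(extra_edges)))
    g = build_ppi(edges)
    if g.number_of_nodes() == 0:
        raise FormatError(f"{path}: empty network after filtering")
    return g


def _read_plain_edges(path: Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            edges.append((parts[0], parts[1]))
    return edges


# Column positions in BioGRID tab3 (0-based): official symbols at 7/8,
# experimental system type at 12, organism ids at 15/16.
_TAB3_SYMBOL_A, _TAB3_SYMBOL_B = 7, 8
_TAB3_SYSTEM_TYPE = 12
_TAB3_ORG_A, _TAB3_ORG_B = 15, 16


def _read_biogrid_tab3(path: Path, taxon: int) -> list[tuple[str, str]]:
    edges = []
    taxon_s = str(taxon)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("#") or line.startswith("BioGRID Interaction ID"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= _TAB3_ORG_B:
                raise FormatError(f"{path}:{lineno}: too few columns for tab3 ({len(parts)})")
            if parts[_TAB3_ORG_A] != taxon_s or parts[_TAB3_ORG_B] != taxon_s:
                continue
            if parts[_TAB3_SYSTEM_TYPE].strip().lower() != "physical":
                continue
            edges.append((parts[_TAB3_SYMBOL_A], parts[_TAB3_SYMBOL_B]))
    return edges


def write_ppi(ppi: nx.Graph, path: str | Path) -> None:
    """Write a PPI network as a sorted two-column TSV (deterministic)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in ppi.edges()):
            fh.write(f"{a}\t{b}\n")


# GMT gene-set collections ----------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered ``{set name: gene list}`` mapping.

    Genes are uppercased and deduplicated within a set (first occurrence
    kept); empty sets are dropped with a warning; duplicate set names and
    lines with fewer than three fields are errors.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(parts)} fields, need >=3")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g.strip().upper() for g in parts[2:] if g.strip()))
            if not genes:
                logger.warning("GMT set %r at %s:%d is empty; dropped", name, path, lineno)
                continue
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\t.\t" + "\t".join(genes) + "\n")


# Tabular readers -------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    return df[list(cols)]


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read SNP-level GWAS summary statistics (SNP, CHROM, POS, P)."""
    df = _require_columns(pd.read_csv(path, sep="\t"), SNP_COLUMNS, path)
    df = df.astype({"SNP": str, "CHROM": str, "POS": int, "P": float})
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise FormatError(f"{path}: duplicate SNP id {dup!r}")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        raise FormatError(f"{path}: SNP p-values must lie in (0, 1]")
    if (df["POS"] < 1).any():
        raise FormatError(f"{path}: positions are 1-based; found POS < 1")
    return df


def read_gene_pvalues(path: str | Path) -> dict[str, float]:
    """Read pre-computed gene-level p-values (GENE, P)."""
    df = _require_columns(pd.read_csv(path, sep="\t"), ["GENE", "P"], path)
    df["GENE"] = df["GENE"].str.upper()
    if df["GENE"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene")
    return dict(zip(df["GENE"], df["P"].astype(float)))


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    df = _require_columns(pd.read_csv(path, sep="\t"), GENE_ANNOT_COLUMNS, path)
    df = df.astype({"GENE": str, "CHROM": str, "START": int, "END": int, "STRAND": str})
    df["GENE"] = df["GENE"].str.upper()
    if df["GENE"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene in annotation")
    if (df["START"] > df["END"]).any():
        raise FormatError(f"{path}: START must be <= END (1-based inclusive)")
    if not df["STRAND"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: STRAND must be '+' or '-'")
    return df


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    df = _require_columns(pd.read_csv(path, sep="\t"), PROBE_ANNOT_COLUMNS, path)
    df = df.astype({"PROBE": str, "CHROM": str, "POS": int, "GENE": str, "STRAND": str})
    df["GENE"] = df["GENE"].str.upper()
    if df["PROBE"].duplicated().any():
        raise FormatError(f"{path}: duplicate probe id")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = _require_columns(pd.read_csv(path, sep="\t"), SAMPLE_SHEET_COLUMNS, path)
    df = df.astype({"SAMPLE": str, "GROUP": str})
    df["GROUP"] = df["GROUP"].str.lower()
    if not df["GROUP"].isin(["case", "control"]).all():
        raise FormatError(f"{path}: GROUP must be 'case' or 'control'")
    return df


def read_matrix(path: str | Path, sep: str = "\t", beta: bool = False,
                max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Read an omics matrix (rows = probes/genes, columns = samples).

    Rows with more than ``max_missing_frac`` missing values are dropped;
    remaining missing values are imputed by the row median.  Beta
    matrices (``beta=True``) are validated to lie in [0, 1].
    """
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate row ids")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    df.index = df.index.astype(str).str.upper()
    frac_missing = df.isna().mean(axis=1)
    dropped = frac_missing > max_missing_frac
    if dropped.any():
        logger.warning("%s: dropped %d rows with >%.0f%% missing values",
                       path, int(dropped.sum()), 100 * max_missing_frac)
        df = df.loc[~dropped]
    if df.isna().any().any():
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
    df = df.astype(float)
    if beta and ((df.values < 0).any() or (df.values > 1).any()):
        raise FormatError(f"{path}: beta values must lie in [0, 1]")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")


def read_mr_table(path: str | Path) -> pd.DataFrame:
    df = _require_columns(pd.read_csv(path, sep="\t"), MR_COLUMNS, path)
    df = df.astype({"SNP": str, "BETA_EXPOSURE": float, "SE_EXPOSURE": float,
                    "BETA_OUTCOME": float, "SE_OUTCOME": float})
    if ((df["SE_EXPOSURE"] <= 0) | (df["SE_OUTCOME"] <= 0)).any():
        raise FormatError(f"{path}: standard errors must be positive")
    return df


def read_gene_scores(path: str | Path) -> pd.DataFrame:
    return _require_columns(pd.read_csv(path, sep="\t"), GENE_SCORE_COLUMNS, path)


def write_gene_scores(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_edge_weights(path: str | Path) -> pd.DataFrame:
    df = _require_columns(pd.read_csv(path, sep="\t"), EDGE_WEIGHT_COLUMNS, path)
    return df.astype({"GENE_A": str, "GENE_B": str, "R_CASE": float,
                      "R_CONTROL": float, "Z_EDGE": float, "SIGNIFICANT": bool})


def write_edge_weights(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# Module output ---------------------------------------------------------------

def write_modules(modules: Sequence[Module], path_prefix: str | Path,
                  ppi: nx.Graph | None = None) -> dict[str, Path]:
    """Write modules as JSON, a TSV summary and per-module SIF edge lists.

    Outputs ``<prefix>.json``, ``<prefix>.tsv`` and ``<prefix>.sif``
    (SIF lines ``geneA<TAB>pp<TAB>geneB`` for each module's PPI-induced
    edges, when ``ppi`` is supplied).  Output is byte-identical across
    runs on identical input.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    json_path = prefix.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump([m.to_dict() for m in modules], fh, indent=1, sort_keys=True)
        fh.write("\n")
    tsv_path = prefix.with_suffix(".tsv")
    rows = [{"ID": m.id, "SEED": m.seed, "SIZE": m.size, "ZM": m.zm,
             "ZN": "NA" if m.zn is None or (isinstance(m.zn, float) and math.isnan(m.zn)) else m.zn,
             "GENES": ",".join(m.genes)} for m in modules]
    pd.DataFrame(rows, columns=["ID", "SEED", "SIZE", "ZM", "ZN", "GENES"]).to_csv(
        tsv_path, sep="\t", index=False, float_format="%.10g")
    sif_path = prefix.with_suffix(".sif")
    with open(sif_path, "w") as fh:
        for m in modules:
            if ppi is None:
                continue
            sub = ppi.subgraph(m.genes)
            for a, b in sorted(tuple(sorted(e)) for e in sub.edges()):
                fh.write(f"{a}\tpp\t{b}\n")
    return {"json": json_path, "tsv": tsv_path, "sif": sif_path}


def read_modules(path: str | Path) -> list[Module]:
    """Read modules back from the JSON produced by :func:`write_modules`."""
    with open(path) as fh:
        data = json.load(fh)
    return [Module.from_dict(d) for d in data]
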