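"""Readers and writers for expression matrices, prior interaction tables
and pathway result tables.

Conventions: genes are rows and cells are columns everywhere; multi-subunit
ligands/receptors are encoded with an underscore separator (``FZD1_LRP5``);
output floats carry six significant digits so re-runs diff cleanly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("xtalkflow")

__all__ = [
    "ExpressionData",
    "LRDatabase",
    "LRRecord",
    "PriorNetworks",
    "read_expression",
    "read_priors",
    "write_pathway_table",
    "read_pathway_table",
    "PATHWAY_COLUMNS",
]

PATHWAY_COLUMNS = [
    "Signal", "SSC", "Target", "S_H", "PA", "PRS",
    "Fid_target_xmod", "Spe_signal_xmod",
]


@dataclass
class ExpressionData:
    """A gene x cell expression matrix with cluster labels.

    ``matrix`` always holds the raw counts; after normalization the
    ``normalized`` (library-size + log1p) and ``scaled`` (per-gene z-score)
    layers are populated and ``state`` advances from ``raw`` to ``scaled``.
    """

    matrix: np.ndarray                      # genes x cells, raw values
    gene_ids: list[str]
    cell_ids: list[str]
    cluster_of: dict[str, str]
    state: str = "raw"
    normalized: np.ndarray | None = None
    scaled: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        missing = [c for c in self.cell_ids if c not in self.cluster_of]
        if missing:
            raise ValueError(f"{len(missing)} cells lack a cluster label")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: j for j, c in enumerate(self.cell_ids)}

    # -- lookups ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.cluster_of[c] for c in self.cell_ids))

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def cells_in(self, cluster: str) -> np.ndarray:
        """Column indices of the cells belonging to a cluster."""
        return np.array(
            [j for j, c in enumerate(self.cell_ids) if self.cluster_of[c] == cluster],
            dtype=int,
        )

    def layer(self, name: str) -> np.ndarray:
        arr = {"raw": self.matrix, "normalized": self.normalized,
               "scaled": self.scaled}[name]
        if arr is None:
            raise ValueError(f"layer {name!r} not computed yet (state={self.state})")
        return arr

    def subset(self, gene_idx: np.ndarray | None = None,
               cell_idx: np.ndarray | None = None) -> "ExpressionData":
        gi = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        sub = ExpressionData(
            matrix=self.matrix[np.ix_(gi, ci)],
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[j] for j in ci],
            cluster_of={self.cell_ids[j]: self.cluster_of[self.cell_ids[j]] for j in ci},
            state=self.state,
        )
        if self.normalized is not None:
            sub.normalized = self.normalized[np.ix_(gi, ci)]
        if self.scaled is not None:
            sub.scaled = self.scaled[np.ix_(gi, ci)]
        return sub


@dataclass
class LRRecord:
    """One ligand-receptor interaction, possibly multi-subunit."""

    ligand_subunits: list[str]
    receptor_subunits: list[str]
    agonists: list[str] = field(default_factory=list)
    antagonists: list[str] = field(default_factory=list)

    @property
    def receptor_name(self) -> str:
        return "_".join(self.receptor_subunits)


@dataclass
class LRDatabase:
    records: list[LRRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class PriorNetworks:
    """Receptor->TF and TF->target prior edge tables.

    Each table has columns ``from``, ``to``, ``weight``; duplicates are
    collapsed keeping the maximum weight and self-loops are dropped.
    """

    receptor_tf_edges: pd.DataFrame
    tf_target_edges: pd.DataFrame

    def __post_init__(self) -> None:
        self.receptor_tf_edges = _clean_edges(self.receptor_tf_edges, "receptor-TF")
        self.tf_target_edges = _clean_edges(self.tf_target_edges, "TF-target")

    @property
    def tfs(self) -> list[str]:
        """TFs present on both sides of the prior route."""
        up = set(self.receptor_tf_edges["to"])
        down = set(self.tf_target_edges["from"])
        return sorted(up & down)


def _clean_edges(df: pd.DataFrame, label: str) -> pd.DataFrame:
    df = df.copy()
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
    bad = ~np.isfinite(df["weight"])
    if bad.any():
        logger.warning("%s: dropping %d edges with non-finite weight", label, bad.sum())
        df = df[~bad]
    loops = df["from"] == df["to"]
    if loops.any():
        logger.warning("%s: dropping %d self-loop edges", label, loops.sum())
        df = df[~loops]
    df = (df.groupby(["from", "to"], as_index=False)["weight"].max()
            .sort_values(["from", "to"], ignore_index=True))
    return df


# ---------------------------------------------------------------------------
# expression input


def read_expression(matrix_path: str | Path, annotation_path: str | Path,
                    genes_path: str | Path | None = None,
                    cells_path: str | Path | None = None) -> ExpressionData:
    """Read a gene x cell matrix plus a (cell, cluster) annotation table.

    ``matrix_path`` may be Matrix Market triplet (``.mtx``, with separate
    one-id-per-line gene and cell files, by default ``genes.txt`` and
    ``cells.txt`` next to it) or a delimited dense table whose header row
    names the cells and whose first column names the genes.

    Cells present in the matrix but missing from the annotation are dropped
    with a logged count; an empty intersection is fatal.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        genes_path = Path(genes_path) if genes_path else matrix_path.parent / "genes.txt"
        cells_path = Path(cells_path) if cells_path else matrix_path.parent / "cells.txt"
        mat = np.asarray(scipy.io.mmread(matrix_path).todense(), dtype=float)
        gene_ids = genes_path.read_text().split()
        cell_ids = cells_path.read_text().split()
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix is {mat.shape} but id files list "
                f"{len(gene_ids)} genes and {len(cell_ids)} cells"
            )
    else:
        sep = "\t" if matrix_path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]

    annot = pd.read_csv(annotation_path, sep=None, engine="python", header=0)
    cluster_of = dict(zip(annot.iloc[:, 0].astype(str), annot.iloc[:, 1].astype(str)))

    keep = [j for j, c in enumerate(cell_ids) if c in cluster_of]
    dropped = len(cell_ids) - len(keep)
    if not keep:
        raise ValueError("no matrix cell appears in the annotation table")
    if dropped:
        logger.warning("dropping %d cells absent from the annotation", dropped)
        mat = mat[:, keep]
        cell_ids = [cell_ids[j] for j in keep]

    return ExpressionData(
        matrix=mat, gene_ids=gene_ids, cell_ids=cell_ids,
        cluster_of={c: cluster_of[c] for c in cell_ids}, state="raw",
    )


# ---------------------------------------------------------------------------
# prior tables


def _split_genes(cell: object, sep: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text or text.lower() == "nan":
        return []
    return [g.strip() for g in text.split(sep) if g.strip()]


def read_priors(lr_path: str | Path, rt_path: str | Path,
                tt_path: str | Path) -> tuple[LRDatabase, PriorNetworks]:
    """Read the ligand-receptor table and the two prior edge tables.

    LR table columns: ``ligand``, ``receptor`` (subunits joined by ``_``),
    optional ``agonist``/``antagonist`` (comma-separated gene lists).  Edge
    tables: ``from``, ``to``, optional ``weight``.  Malformed rows are
    skipped with a warning; an empty file is fatal.
    """
    lr_df = pd.read_csv(lr_path, sep=None, engine="python")
    lr_df.columns = [c.strip().lower() for c in lr_df.columns]
    records: list[LRRecord] = []
    for _, row in lr_df.iterrows():
        lig = _split_genes(row.get("ligand"), "_")
        rec = _split_genes(row.get("receptor"), "_")
        if not lig or not rec:
            logger.warning("skipping malformed LR row: %s", row.to_dict())
            continue
        records.append(LRRecord(
            ligand_subunits=lig,
            receptor_subunits=rec,
            agonists=_split_genes(row.get("agonist"), ","),
            antagonists=_split_genes(row.get("antagonist"), ","),
        ))
    if not records:
        raise ValueError(f"no usable ligand-receptor records in {lr_path}")

    nets = []
    for path, label in ((rt_path, "receptor-TF"), (tt_path, "TF-target")):
        df = pd.read_csv(path, sep=None, engine="python")
        df.columns = [c.strip().lower() for c in df.columns]
        if not {"from", "to"}.issubset(df.columns):
            raise ValueError(f"{path}: edge table needs 'from' and 'to' columns")
        df = df.dropna(subset=["from", "to"])
        df["from"] = df["from"].astype(str)
        df["to"] = df["to"].astype(str)
        if df.empty:
            raise ValueError(f"{path}: empty {label} edge table")
        nets.append(df)

    return LRDatabase(records), PriorNetworks(nets[0], nets[1])


# ---------------------------------------------------------------------------
# pathway table output


def _fmt(x: object) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_pathway_table(paths: pd.DataFrame, out_path: str | Path) -> None:
    """Write the pathway table as TSV with a fixed column set and row order.

    Rows are sorted lexicographically by (Signal, SSC, Target); floats use
    six significant digits; not-yet-computed columns are empty strings, so
    writing the same table twice gives byte-identical files.
    """
    df = paths.copy()
    for col in PATHWAY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[PATHWAY_COLUMNS].sort_values(
        ["Signal", "SSC", "Target"], ignore_index=True)
    out = df.copy()
    for col in ["S_H", "PA", "PRS", "Fid_target_xmod", "Spe_signal_xmod"]:
        out[col] = [_fmt(float(v)) if pd.notna(v) else "" for v in df[col]]
    out.to_csv(out_path, sep="\t", index=False, lineterminator="\n")


def read_pathway_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("Signal", "SSC", "Target")})
    for col in ["S_H", "PA", "PRS", "Fid_target_xmod", "Spe_signal_xmod"]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
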