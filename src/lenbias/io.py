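"""Reading and writing the experiment exchange formats, plus QC filtering.

On disk an experiment is a Matrix Market ``matrix.mtx`` (genes x cells,
integer, 1-based per the MTX dialect) with ``genes.tsv`` / ``cells.tsv``
sidecars and, for simulated data, a ``truth.json`` ledger.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    TECHNIQUES,
    CellRecord,
    EmptyResultError,
    FormatError,
    GeneStructure,
    PairedExperiment,
    QCThresholds,
    SimulationTruth,
)

GENE_COLUMNS = [
    "gene_id",
    "symbol",
    "exon_count",
    "transcript_length",
    "cds_length",
    "genomic_span",
    "is_mito",
    "is_ribo",
]
CELL_COLUMNS = ["cell_id", "technique", "cluster", "total_counts", "n_features"]


def write_experiment(exp: PairedExperiment, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx + genes.tsv + cells.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mtx = out / "matrix.mtx"
    scipy.io.mmwrite(mtx, exp.counts.astype(np.int64), field="integer")
    genes = exp.genes_frame()[GENE_COLUMNS].copy()
    genes["is_mito"] = genes["is_mito"].astype(int)
    genes["is_ribo"] = genes["is_ribo"].astype(int)
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    exp.cells_frame()[CELL_COLUMNS].to_csv(out / "cells.tsv", sep="\t", index=False)
    return {"mtx": mtx, "genes": out / "genes.tsv", "cells": out / "cells.tsv"}


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SimulationTruth:
    return SimulationTruth.from_dict(json.loads(Path(path).read_text()))


def read_experiment(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> PairedExperiment:
    """Read and validate an experiment from its three files.

    Depth metadata (total_counts, n_features) is recomputed from the
    matrix and compared against the cells.tsv record; a mismatch is a
    format error naming the offending file.
    """
    try:
        counts = sp.csc_matrix(scipy.io.mmread(str(mtx_path)))
    except Exception as e:  # malformed MTX
        raise FormatError(f"{mtx_path}: cannot parse Matrix Market file ({e})") from e
    if counts.nnz and counts.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative count entries")

    genes_df = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str, "symbol": str})
    missing = set(GENE_COLUMNS) - set(genes_df.columns)
    if missing:
        raise FormatError(f"{genes_path}: missing columns {sorted(missing)}")
    if len(genes_df) != counts.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(genes_df)} rows but matrix has {counts.shape[0]} genes"
        )

    cells_df = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str, "cluster": str})
    missing = set(CELL_COLUMNS) - set(cells_df.columns)
    if missing:
        raise FormatError(f"{cells_path}: missing columns {sorted(missing)}")
    if len(cells_df) != counts.shape[1]:
        raise FormatError(
            f"{cells_path}: {len(cells_df)} rows but matrix has {counts.shape[1]} cells"
        )
    bad_tech = set(cells_df["technique"]) - set(TECHNIQUES)
    if bad_tech:
        raise FormatError(f"{cells_path}: unknown technique labels {sorted(bad_tech)}")

    genes = [
        GeneStructure(
            gene_id=r.gene_id,
            symbol=r.symbol,
            exon_count=int(r.exon_count),
            transcript_length=int(r.transcript_length),
            cds_length=int(r.cds_length),
            genomic_span=int(r.genomic_span),
            is_mito=bool(int(r.is_mito)),
            is_ribo=bool(int(r.is_ribo)),
        )
        for r in genes_df.itertuples()
    ]
    cells = [
        CellRecord(
            cell_id=r.cell_id,
            technique=r.technique,
            cluster=str(r.cluster),
            total_counts=int(r.total_counts),
            n_features=int(r.n_features),
        )
        for r in cells_df.itertuples()
    ]
    exp = PairedExperiment(counts, genes, cells, validate=False)
    try:
        exp.validate()
    except FormatError as e:
        raise FormatError(f"{cells_path}: {e}") from e
    return exp


def read_gene_annotation(path: str | Path) -> list[GeneStructure]:
    """Read a standalone per-gene structure table (same columns as genes.tsv)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneStructure(
            r.gene_id, r.symbol, int(r.exon_count), int(r.transcript_length),
            int(r.cds_length), int(r.genomic_span), bool(int(r.is_mito)),
            bool(int(r.is_ribo)),
        )
        for r in df.itertuples()
    ]


def filter_matrix(exp: PairedExperiment, thresholds: QCThresholds) -> PairedExperiment:
    """Single-pass QC: drop under-detected genes, then under-complex cells.

    Genes nonzero in fewer than ``min_cells_per_gene`` cells are removed
    first; cells with fewer than ``min_features_per_cell`` nonzero genes
    (counted on the retained genes) are removed second. The pass is not
    iterated. Depth metadata is re-derived.
    """
    gene_cells = exp.counts.getnnz(axis=1)
    keep_genes = np.nonzero(gene_cells >= thresholds.min_cells_per_gene)[0]
    sub = exp.counts[keep_genes, :]
    cell_feats = sub.getnnz(axis=0)
    keep_cells = np.nonzero(cell_feats >= thresholds.min_features_per_cell)[0]
    if keep_cells.size == 0 or keep_genes.size == 0:
        raise EmptyResultError(
            f"QC removed everything (kept {keep_genes.size} genes, {keep_cells.size} cells)"
        )
    return exp.subset(gene_idx=keep_genes, cell_idx=keep_cells)
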