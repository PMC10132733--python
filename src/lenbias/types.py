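"""Core domain objects shared by every pipeline stage.

The central container is :class:`PairedExperiment`: a sparse gene x cell
count matrix whose rows are described by :class:`GeneStructure` records
(structural annotation: exon count, lengths, genomic span, compartment
flags) and whose columns are described by :class:`CellRecord` entries
(technique, cluster, depth).  All downstream stages — QC, normalization,
depth-matched subsampling, differential expression, structural-bias
scoring and enrichment — transform or consume this object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

SINGLE_CELL = "single_cell"
SINGLE_NUCLEUS = "single_nucleus"
TECHNIQUES = (SINGLE_CELL, SINGLE_NUCLEUS)


class LenbiasError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(LenbiasError, ValueError):
    pass


class FormatError(LenbiasError, ValueError):
    """A file on disk violates the expected format or is inconsistent."""


class InsufficientDataError(LenbiasError, ValueError):
    pass


class EmptyResultError(LenbiasError, ValueError):
    pass


@dataclass(frozen=True)
class GeneStructure:
    """Structural annotation of one gene (representative transcript).

    ``transcript_length`` is the summed exon length of the mature
    transcript, ``genomic_span`` the first-to-last-exon footprint
    (introns included), ``cds_length`` the protein-coding portion.
    """

    gene_id: str
    symbol: str
    exon_count: int
    transcript_length: int
    cds_length: int
    genomic_span: int
    is_mito: bool = False
    is_ribo: bool = False

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise InvalidArgumentError(f"{self.gene_id}: exon_count must be >= 1")
        if self.transcript_length <= 0 or self.genomic_span <= 0:
            raise InvalidArgumentError(f"{self.gene_id}: lengths must be positive")
        if self.cds_length < 0:
            raise InvalidArgumentError(f"{self.gene_id}: cds_length must be >= 0")
        if not (self.cds_length <= self.transcript_length <= self.genomic_span):
            raise InvalidArgumentError(
                f"{self.gene_id}: need cds <= transcript <= span, got "
                f"{self.cds_length}/{self.transcript_length}/{self.genomic_span}"
            )
        if self.exon_count == 1 and self.transcript_length != self.genomic_span:
            raise InvalidArgumentError(
                f"{self.gene_id}: single-exon gene must have transcript_length == genomic_span"
            )
        if self.is_mito and self.is_ribo:
            raise InvalidArgumentError(f"{self.gene_id}: is_mito and is_ribo are exclusive")


@dataclass(frozen=True)
class CellRecord:
    """Per-cell metadata: technique, cluster label and realized depth."""

    cell_id: str
    technique: str
    cluster: str
    total_counts: int
    n_features: int

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise InvalidArgumentError(
                f"{self.cell_id}: unknown technique {self.technique!r}"
            )
        if self.total_counts < 0 or self.n_features < 0:
            raise InvalidArgumentError(f"{self.cell_id}: negative depth fields")
        if self.total_counts > 0 and self.n_features > self.total_counts:
            raise InvalidArgumentError(
                f"{self.cell_id}: n_features ({self.n_features}) exceeds "
                f"total_counts ({self.total_counts})"
            )


STRUCTURE_FEATURES = ("exon_count", "transcript_length", "cds_length", "genomic_span")


def catalog_to_frame(catalog: Sequence[GeneStructure]) -> pd.DataFrame:
    """Tabulate a gene catalog, indexed by gene_id."""
    df = pd.DataFrame([asdict(g) for g in catalog])
    return df.set_index("gene_id", drop=False)


class PairedExperiment:
    """Sparse count matrix plus gene/cell metadata for two techniques.

    Rows follow ``genes`` order, columns follow ``cells`` order. Counts
    are stored CSC so that per-cell (column) operations used throughout
    the pipeline never materialize zeros.
    """

    def __init__(
        self,
        counts: sp.spmatrix,
        genes: Sequence[GeneStructure],
        cells: Sequence[CellRecord],
        validate: bool = True,
    ) -> None:
        counts = sp.csc_matrix(counts)
        if counts.shape != (len(genes), len(cells)):
            raise InvalidArgumentError(
                f"counts shape {counts.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        self.counts = counts
        self.genes = list(genes)
        self.cells = list(cells)
        if validate:
            self.validate()

    # -- derived views -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def technique_labels(self) -> np.ndarray:
        return np.array([c.technique for c in self.cells])

    def cluster_labels(self) -> np.ndarray:
        return np.array([c.cluster for c in self.cells])

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.int64)

    def n_features(self) -> np.ndarray:
        return self.counts.getnnz(axis=0).astype(np.int64)

    def technique_mask(self, technique: str) -> np.ndarray:
        if technique not in TECHNIQUES:
            raise InvalidArgumentError(f"unknown technique {technique!r}")
        return self.technique_labels() == technique

    def genes_frame(self) -> pd.DataFrame:
        return catalog_to_frame(self.genes)

    def cells_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(c) for c in self.cells])
        return df.set_index("cell_id", drop=False)

    # -- validation / rebuilding ---------------------------------------
    def validate(self) -> None:
        if (self.counts.data < 0).any():
            raise InvalidArgumentError("count matrix contains negative entries")
        if not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise InvalidArgumentError("count matrix contains non-integer entries")
        totals = self.total_counts()
        feats = self.n_features()
        for j, cell in enumerate(self.cells):
            if cell.total_counts != totals[j]:
                raise FormatError(
                    f"cell {cell.cell_id}: recorded total_counts {cell.total_counts} "
                    f"!= column sum {totals[j]}"
                )
            if cell.n_features != feats[j]:
                raise FormatError(
                    f"cell {cell.cell_id}: recorded n_features {cell.n_features} "
                    f"!= nonzero genes {feats[j]}"
                )

    @staticmethod
    def from_matrix(
        counts: sp.spmatrix,
        genes: Sequence[GeneStructure],
        cell_ids: Sequence[str],
        techniques: Sequence[str],
        clusters: Sequence[str],
    ) -> "PairedExperiment":
        """Build an experiment deriving total_counts/n_features from the matrix."""
        counts = sp.csc_matrix(counts)
        counts.eliminate_zeros()
        totals = np.asarray(counts.sum(axis=0)).ravel().astype(np.int64)
        feats = counts.getnnz(axis=0)
        cells = [
            CellRecord(cid, tech, str(cl), int(t), int(f))
            for cid, tech, cl, t, f in zip(cell_ids, techniques, clusters, totals, feats)
        ]
        return PairedExperiment(counts, genes, cells)

    def subset(self, gene_idx: np.ndarray | None = None, cell_idx: np.ndarray | None = None) -> "PairedExperiment":
        """Row/column subset; depth metadata is re-derived from the submatrix."""
        counts = self.counts
        genes = self.genes
        cells = self.cells
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            counts = counts[gene_idx, :]
            genes = [self.genes[i] for i in gene_idx]
        if cell_idx is not None:
            cell_idx = np.asarray(cell_idx)
            counts = counts[:, cell_idx]
            cells = [self.cells[j] for j in cell_idx]
        return PairedExperiment.from_matrix(
            counts,
            genes,
            [c.cell_id for c in cells],
            [c.technique for c in cells],
            [c.cluster for c in cells],
        )

    def to_anndata(self):
        """Convert to an AnnData (cells x genes) for interop with scanpy."""
        import anndata as ad

        adata = ad.AnnData(
            X=sp.csr_matrix(self.counts.T),
            obs=self.cells_frame().drop(columns="cell_id"),
            var=self.genes_frame().drop(columns="gene_id"),
        )
        return adata


@dataclass
class SimulationTruth:
    """Planted generator parameters: the ground truth recovery is judged against.

    ``bias_amplitude`` is the plateau of the logistic capture-efficiency
    curve applied to the single-nucleus technique; amplitude 1 defines the
    null generator (techniques exchangeable).  ``bias_midpoint`` is in
    exons; the curve crosses halfway between 1 and the amplitude there.
    ``baseline_dispersion`` is the negative-binomial size parameter theta
    of the per-gene-per-cell gamma perturbation (math.inf = none).
    """

    seed: int = 0
    n_genes: int = 2000
    n_cells_per_technique: int = 2000
    n_clusters: int = 3
    bias_midpoint: float = 10.0
    bias_steepness: float = 0.7
    bias_amplitude: float = 4.0
    marker_table: dict[str, tuple[tuple[str, ...], float]] = field(default_factory=dict)
    libsize_log_mean: float = math.log(1500.0)
    libsize_log_sd: float = 0.22
    baseline_dispersion: float = 10.0
    base_expression_log_sd: float = 1.0
    mito_fraction: float = 0.005
    ribo_fraction: float = 0.02
    compartment_boost: float = 8.0
    single_cell_length_tilt: float = 0.0
    technique_fold_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bias_amplitude < 1:
            raise InvalidArgumentError("bias_amplitude must be >= 1")
        if not self.baseline_dispersion > 0:
            raise InvalidArgumentError("baseline_dispersion must be > 0 (math.inf allowed)")
        if self.n_genes < 1 or self.n_cells_per_technique < 1 or self.n_clusters < 1:
            raise InvalidArgumentError("simulation sizes must be positive")
        for cl, (genes, fc) in self.marker_table.items():
            if fc <= 1:
                raise InvalidArgumentError(f"cluster {cl}: marker fold change must be > 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marker_table"] = {
            cl: {"genes": list(genes), "fold_change": fc}
            for cl, (genes, fc) in self.marker_table.items()
        }
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "SimulationTruth":
        d = dict(d)
        mt = d.get("marker_table", {})
        d["marker_table"] = {
            cl: (tuple(v["genes"]), float(v["fold_change"])) for cl, v in mt.items()
        }
        return SimulationTruth(**d)


@dataclass(frozen=True)
class QCThresholds:
    """Minimum-evidence filters: genes seen in >= min_cells_per_gene cells,
    cells expressing >= min_features_per_cell genes."""

    min_cells_per_gene: int = 5
    min_features_per_cell: int = 300

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0 or self.min_features_per_cell < 0:
            raise InvalidArgumentError("QC thresholds must be >= 0")


@dataclass(frozen=True)
class DepthWindow:
    """Per-technique exclusive (min_counts, max_counts) library-size window."""

    bounds: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for tech, (lo, hi) in self.bounds.items():
            if tech not in TECHNIQUES:
                raise InvalidArgumentError(f"unknown technique {tech!r}")
            if not (0 < lo < hi):
                raise InvalidArgumentError(f"{tech}: need 0 < min < max, got ({lo}, {hi})")

    def mask(self, totals: np.ndarray, techniques: np.ndarray) -> np.ndarray:
        """Boolean in-window mask (exclusive bounds) per cell."""
        out = np.zeros(len(totals), dtype=bool)
        for tech, (lo, hi) in self.bounds.items():
            sel = techniques == tech
            out[sel] = (totals[sel] > lo) & (totals[sel] < hi)
        return out

    @staticmethod
    def symmetric(lo: int, hi: int) -> "DepthWindow":
        return DepthWindow({t: (lo, hi) for t in TECHNIQUES})


@dataclass(frozen=True)
class MarkerFilter:
    """Testing filters for marker detection.

    ``min_pct`` — a gene is tested only if expressed in at least this
    fraction of cells in one of the two groups; ``logfc_threshold`` — and
    only if the absolute natural-log fold change exceeds this;
    ``exclude_prefixes`` — symbol prefixes removed from top lists
    (mitochondrial and ribosomal-protein genes, absent from nuclei).
    """

    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    positive_only: bool = True
    exclude_prefixes: tuple[str, ...] = ("mt-", "Rpl", "Rps")

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_pct <= 1.0):
            raise InvalidArgumentError("min_pct must be in [0, 1]")
        if self.logfc_threshold < 0:
            raise InvalidArgumentError("logfc_threshold must be >= 0")


@dataclass(frozen=True)
class DEGRecord:
    """One gene's between-group test result, oriented toward ``group``
    (log_fc > 0 means higher in ``group``)."""

    gene_id: str
    symbol: str
    group: str
    log_fc: float
    p_value: float
    p_adj: float
    pct_in: float
    pct_out: float


@dataclass(frozen=True)
class GeneSet:
    """Named gene set (e.g. one GMT line)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidArgumentError(f"gene set {self.name!r} is empty")
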