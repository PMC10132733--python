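"""Synthetic paired single-cell / single-nucleus experiments with a planted,
parameterized gene-length capture bias.

The generator emulates the features the downstream analysis exercises:

* a gene catalog whose exon counts follow a shifted negative binomial
  targeting the genome-wide average of ~8.8 exons per gene, with exon and
  intron lengths drawn log-normally so that transcript length, CDS length
  and genomic span are realistically correlated with exon count;
* mitochondrial ("mt-") and ribosomal-protein ("Rpl"/"Rps") genes that are
  highly expressed in whole cells but entirely absent from nuclei;
* shared cell populations (clusters) with planted fold-change markers;
* log-normal library-size variation;
* a technique-specific capture-efficiency curve: for the nucleus technique
  a logistic increase in exon count with midpoint ~10 exons, for the
  whole-cell technique flat by default (optional inverse-length tilt).

Counts are drawn per cell from a single multinomial over the normalized
product of base expression, cluster-marker fold change and capture weight,
so library size is exactly controllable; overdispersion enters through an
optional per-gene-per-cell gamma perturbation (negative-binomial size
``baseline_dispersion``).
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import scipy.sparse as sp

from .types import (
    SINGLE_CELL,
    SINGLE_NUCLEUS,
    CellRecord,
    GeneStructure,
    InvalidArgumentError,
    PairedExperiment,
    SimulationTruth,
)

# catalog distribution settings (see docs/methods.md for rationale)
EXON_COUNT_NB_MEAN = 7.8  # exon_count = 1 + NB(mean, size)
EXON_COUNT_NB_SIZE = 2.0
EXON_LEN_LOG_MEAN = math.log(160.0)
EXON_LEN_LOG_SD = 0.7
INTRON_LEN_LOG_MEAN = math.log(1500.0)
INTRON_LEN_LOG_SD = 1.0


def simulate_gene_catalog(
    n_genes: int,
    seed: int,
    mito_fraction: float = 0.005,
    ribo_fraction: float = 0.02,
    gene_prefix: str = "G",
    mito_prefix: str = "mt-",
    ribo_prefixes: tuple[str, str] = ("Rpl", "Rps"),
) -> list[GeneStructure]:
    """Draw a synthetic per-gene structure catalog.

    Mitochondrial genes are intronless (exon_count forced to 1, so
    transcript length equals genomic span); ribosomal-protein genes are
    short with at most 6 exons. Deterministic for a fixed seed.
    """
    if n_genes < 50:
        raise InvalidArgumentError("n_genes must be >= 50")
    if mito_fraction < 0 or ribo_fraction < 0 or mito_fraction + ribo_fraction > 0.5:
        raise InvalidArgumentError("compartment fractions must be >= 0 and sum to <= 0.5")
    rng = np.random.default_rng(seed)

    p = EXON_COUNT_NB_SIZE / (EXON_COUNT_NB_SIZE + EXON_COUNT_NB_MEAN)
    exons = 1 + rng.negative_binomial(EXON_COUNT_NB_SIZE, p, size=n_genes)

    n_mito = int(round(mito_fraction * n_genes))
    n_ribo = int(round(ribo_fraction * n_genes))
    flags = np.zeros(n_genes, dtype=np.int8)  # 0 plain, 1 mito, 2 ribo
    special = rng.choice(n_genes, size=n_mito + n_ribo, replace=False)
    mito_idx, ribo_idx = special[:n_mito], special[n_mito:]
    flags[mito_idx] = 1
    flags[ribo_idx] = 2
    exons[mito_idx] = 1
    exons[ribo_idx] = rng.integers(2, 7, size=n_ribo)

    genes: list[GeneStructure] = []
    n_ribo_seen = 0
    for i in range(n_genes):
        k = int(exons[i])
        exon_lens = np.rint(rng.lognormal(EXON_LEN_LOG_MEAN, EXON_LEN_LOG_SD, size=k))
        exon_lens = np.maximum(exon_lens, 30).astype(np.int64)
        tx_len = int(exon_lens.sum())
        if k > 1:
            intron_lens = np.rint(
                rng.lognormal(INTRON_LEN_LOG_MEAN, INTRON_LEN_LOG_SD, size=k - 1)
            )
            intron_lens = np.maximum(intron_lens, 60).astype(np.int64)
            span = tx_len + int(intron_lens.sum())
        else:
            span = tx_len
        cds = int(math.floor(rng.uniform(0.3, 0.9) * tx_len))
        if flags[i] == 1:
            symbol = f"{mito_prefix}{gene_prefix}{i}"
        elif flags[i] == 2:
            symbol = f"{ribo_prefixes[n_ribo_seen % 2]}{gene_prefix}{i}"
            n_ribo_seen += 1
        else:
            symbol = f"{gene_prefix}{i}"
        genes.append(
            GeneStructure(
                gene_id=f"{gene_prefix}{i:05d}",
                symbol=symbol,
                exon_count=k,
                transcript_length=tx_len,
                cds_length=cds,
                genomic_span=span,
                is_mito=bool(flags[i] == 1),
                is_ribo=bool(flags[i] == 2),
            )
        )
    return genes


def nucleus_capture_weight(
    exon_count: np.ndarray,
    amplitude: float,
    midpoint: float,
    steepness: float,
) -> np.ndarray:
    """Logistic capture-efficiency curve for the nucleus technique.

    1 + (amplitude - 1) * sigmoid(steepness * (exon_count - midpoint)):
    short genes near weight 1, genes past the midpoint approach the
    amplitude. Amplitude 1 gives the flat (null) curve.
    """
    e = np.asarray(exon_count, dtype=float)
    return 1.0 + (amplitude - 1.0) / (1.0 + np.exp(-steepness * (e - midpoint)))


def default_marker_table(
    catalog: list[GeneStructure],
    n_clusters: int,
    rng: np.random.Generator,
    markers_per_cluster: int = 15,
    fold_change: float = 4.0,
) -> dict[str, tuple[tuple[str, ...], float]]:
    """Assign disjoint random non-compartment genes as cluster markers."""
    plain = [g.gene_id for g in catalog if not (g.is_mito or g.is_ribo)]
    need = markers_per_cluster * n_clusters
    if need > len(plain):
        raise InvalidArgumentError("not enough genes for the requested marker table")
    chosen = rng.choice(len(plain), size=need, replace=False)
    table = {}
    for c in range(n_clusters):
        ids = tuple(plain[i] for i in chosen[c * markers_per_cluster : (c + 1) * markers_per_cluster])
        table[f"c{c}"] = (ids, fold_change)
    return table


def simulate_paired_experiment(
    catalog: list[GeneStructure],
    truth: SimulationTruth,
) -> tuple[PairedExperiment, SimulationTruth]:
    """Generate a paired experiment with the planted capture bias.

    Returns the experiment together with the (possibly completed) truth
    ledger: if ``truth.marker_table`` is empty a default table is drawn
    and recorded. All randomness flows from ``truth.seed``.
    """
    if not catalog:
        raise InvalidArgumentError("catalog must be nonempty")
    if truth.bias_amplitude < 1:
        raise InvalidArgumentError("bias_amplitude must be >= 1")
    if len(catalog) != truth.n_genes:
        truth = replace(truth, n_genes=len(catalog))
    rng = np.random.default_rng(truth.seed)

    n_genes = len(catalog)
    exon_counts = np.array([g.exon_count for g in catalog], dtype=float)
    tx_len = np.array([g.transcript_length for g in catalog], dtype=float)
    mito = np.array([g.is_mito for g in catalog])
    ribo = np.array([g.is_ribo for g in catalog])
    gene_ids = [g.gene_id for g in catalog]
    gene_index = {gid: i for i, gid in enumerate(gene_ids)}

    # per-gene base expression; compartment genes are abundant in whole cells
    base = rng.lognormal(0.0, truth.base_expression_log_sd, size=n_genes)
    base[mito | ribo] *= truth.compartment_boost

    if not truth.marker_table:
        truth = replace(
            truth, marker_table=default_marker_table(catalog, truth.n_clusters, rng)
        )

    # capture weights per technique
    w_nuc = nucleus_capture_weight(
        exon_counts, truth.bias_amplitude, truth.bias_midpoint, truth.bias_steepness
    )
    for gid, fc in truth.technique_fold_changes.items():
        w_nuc[gene_index[gid]] *= fc
    w_nuc[mito | ribo] = 0.0
    w_cell = np.ones(n_genes)
    if truth.single_cell_length_tilt != 0.0:
        w_cell = (tx_len / np.median(tx_len)) ** (-truth.single_cell_length_tilt)
    capture = {SINGLE_CELL: w_cell, SINGLE_NUCLEUS: w_nuc}

    # cluster fold-change multipliers
    clusters = sorted(truth.marker_table)
    cluster_mult = {cl: np.ones(n_genes) for cl in clusters}
    for cl, (ids, fc) in truth.marker_table.items():
        for gid in ids:
            cluster_mult[cl][gene_index[gid]] = fc

    n_per = truth.n_cells_per_technique
    techniques = np.repeat([SINGLE_CELL, SINGLE_NUCLEUS], n_per)
    cell_clusters = rng.choice(clusters, size=2 * n_per)
    libsizes = np.maximum(
        1, np.rint(rng.lognormal(truth.libsize_log_mean, truth.libsize_log_sd, size=2 * n_per))
    ).astype(np.int64)

    perturb = math.isfinite(truth.baseline_dispersion)
    theta = truth.baseline_dispersion

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for j in range(2 * n_per):
        w = base * cluster_mult[cell_clusters[j]] * capture[techniques[j]]
        if perturb:
            w = w * rng.gamma(theta, 1.0 / theta, size=n_genes)
        p = w / w.sum()
        counts_j = rng.multinomial(libsizes[j], p)
        nz = np.nonzero(counts_j)[0]
        rows.append(nz)
        cols.append(np.full(nz.size, j, dtype=np.int64))
        data.append(counts_j[nz])

    counts = sp.csc_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_genes, 2 * n_per),
        dtype=np.int64,
    )
    cell_ids = [f"{techniques[j][:2]}_{j:05d}" for j in range(2 * n_per)]
    exp = PairedExperiment.from_matrix(counts, catalog, cell_ids, techniques, cell_clusters)
    return exp, truth


def null_experiment(
    catalog: list[GeneStructure], truth: SimulationTruth
) -> tuple[PairedExperiment, SimulationTruth]:
    """Convenience wrapper forcing the null generator (no technique bias).

    Compartment-exclusion is also disabled so the two techniques are fully
    exchangeable and any between-technique statistic has its nominal null
    distribution.
    """
    null_truth = replace(
        truth, bias_amplitude=1.0, technique_fold_changes={}, mito_fraction=0.0,
        ribo_fraction=0.0,
    )
    # catalog may still contain compartment genes; neutralize their flags'
    # effect by treating them as plain genes (weight 1 in both techniques).
    plain_catalog = [
        g
        if not (g.is_mito or g.is_ribo)
        else GeneStructure(
            g.gene_id, g.symbol.replace("mt-", "n-").replace("Rpl", "nl").replace("Rps", "ns"),
            g.exon_count, g.transcript_length, g.cds_length, g.genomic_span,
        )
        for g in catalog
    ]
    return simulate_paired_experiment(plain_catalog, null_truth)


def default_truth(seed: int = 0, **overrides) -> SimulationTruth:
    """The package's reference simulation conditions (see docs/methods.md)."""
    return SimulationTruth(seed=seed, **overrides)
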