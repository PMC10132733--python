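import numpy as np
import pytest
import scipy.sparse as sp

from lenbias.types import GeneStructure, PairedExperiment, SimulationTruth
from lenbias.simulate import simulate_gene_catalog, simulate_paired_experiment


def make_genes(n: int, exon_counts=None, symbols=None) -> list[GeneStructure]:
    """Minimal valid single-exon gene catalog for handcrafted matrices."""
    genes = []
    for i in range(n):
        k = 1 if exon_counts is None else int(exon_counts[i])
        tx = 100 * k
        span = tx if k == 1 else tx + 500 * (k - 1)
        sym = f"T{i}" if symbols is None else symbols[i]
        genes.append(GeneStructure(f"T{i:04d}", sym, k, tx, 50, span))
    return genes


def make_experiment(counts, techniques=None, clusters=None, genes=None) -> PairedExperiment:
    """Build a PairedExperiment from a dense count array (genes x cells)."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if genes is None:
        genes = make_genes(n_genes)
    if techniques is None:
        half = n_cells // 2
        techniques = ["single_cell"] * half + ["single_nucleus"] * (n_cells - half)
    if clusters is None:
        clusters = ["c0"] * n_cells
    return PairedExperiment.from_matrix(
        sp.csc_matrix(counts), genes,
        [f"cell{j}" for j in range(n_cells)], techniques, clusters,
    )


@pytest.fixture(scope="session")
def small_catalog():
    return simulate_gene_catalog(300, seed=42)


@pytest.fixture(scope="session")
def small_biased_run():
    """One modest biased experiment shared by several test modules."""
    truth = SimulationTruth(seed=5, n_genes=600, n_cells_per_technique=250,
                            bias_amplitude=4.0)
    catalog = simulate_gene_catalog(600, seed=5, mito_fraction=truth.mito_fraction,
                                    ribo_fraction=truth.ribo_fraction)
    exp, truth = simulate_paired_experiment(catalog, truth)
    return exp, truth
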