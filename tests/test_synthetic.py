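"""Generator contracts: catalog realism, determinism, planted-bias mechanics."""

import numpy as np
import pytest

import lenbias as lb
from lenbias.simulate import nucleus_capture_weight, simulate_gene_catalog, simulate_paired_experiment
from lenbias.types import SimulationTruth, catalog_to_frame


def test_catalog_targets_genome_mean_exon_count():
    cat = simulate_gene_catalog(10_000, seed=1)
    mean_exons = catalog_to_frame(cat)["exon_count"].mean()
    assert 8.3 <= mean_exons <= 9.3


def test_catalog_structural_invariants(small_catalog):
    for g in small_catalog:
        assert g.cds_length <= g.transcript_length <= g.genomic_span
        assert g.exon_count >= 1
        if g.exon_count == 1:
            assert g.transcript_length == g.genomic_span
        assert not (g.is_mito and g.is_ribo)
        if g.is_mito:
            assert g.exon_count == 1 and g.symbol.startswith("mt-")
        if g.is_ribo:
            assert g.exon_count <= 6 and g.symbol.startswith(("Rpl", "Rps"))


def test_catalog_deterministic_for_fixed_seed():
    assert simulate_gene_catalog(200, seed=9) == simulate_gene_catalog(200, seed=9)
    assert simulate_gene_catalog(200, seed=9) != simulate_gene_catalog(200, seed=10)


def test_catalog_rejects_tiny_n():
    with pytest.raises(lb.InvalidArgumentError):
        simulate_gene_catalog(10, seed=0)


def test_truth_validation():
    with pytest.raises(lb.InvalidArgumentError):
        SimulationTruth(bias_amplitude=0.5)
    with pytest.raises(lb.InvalidArgumentError):
        SimulationTruth(marker_table={"c0": (("g1",), 0.9)})


def test_experiment_depth_metadata_exact(small_biased_run):
    exp, _ = small_biased_run
    totals = exp.total_counts()
    feats = exp.n_features()
    for j, cell in enumerate(exp.cells):
        assert cell.total_counts == totals[j]
        assert cell.n_features == feats[j]
        assert 0 < cell.n_features <= cell.total_counts


def test_compartment_genes_absent_from_nucleus(small_biased_run):
    exp, _ = small_biased_run
    nuc = exp.technique_mask("single_nucleus")
    cell = exp.technique_mask("single_cell")
    comp = np.array([g.is_mito or g.is_ribo for g in exp.genes])
    assert comp.any()
    sub = exp.counts[np.nonzero(comp)[0], :]
    assert sub[:, np.nonzero(nuc)[0]].nnz == 0
    assert sub[:, np.nonzero(cell)[0]].nnz > 0


def test_capture_weight_monotone_in_exon_count():
    exons = np.arange(1, 80)
    w = nucleus_capture_weight(exons, amplitude=4.0, midpoint=10.0, steepness=0.7)
    assert np.all(np.diff(w) >= 0)
    assert w[0] >= 1.0 and w[-1] <= 4.0
    assert np.allclose(nucleus_capture_weight(exons, 1.0, 10.0, 0.7), 1.0)


def test_experiment_deterministic_for_fixed_seed(small_catalog):
    truth = SimulationTruth(seed=3, n_genes=300, n_cells_per_technique=60)
    e1, t1 = simulate_paired_experiment(small_catalog, truth)
    e2, t2 = simulate_paired_experiment(small_catalog, truth)
    assert (e1.counts != e2.counts).nnz == 0
    assert e1.cells == e2.cells
    assert t1.marker_table == t2.marker_table


def test_null_generator_two_proportion_z_is_standard_normal(small_catalog):
    """Without planted bias or gamma noise the techniques split counts
    binomially, so per-gene two-proportion z-scores are ~N(0,1)."""
    # one cluster and no gamma noise: every count is an iid multinomial draw
    # from one shared gene distribution, so the binomial z reference applies
    truth = SimulationTruth(seed=21, n_genes=300, n_cells_per_technique=300,
                            bias_amplitude=1.0, baseline_dispersion=np.inf,
                            n_clusters=1)
    exp, _ = lb.null_experiment(small_catalog, truth)
    tech = exp.technique_labels()
    x1 = np.asarray(exp.counts[:, tech == "single_cell"].sum(axis=1)).ravel()
    x2 = np.asarray(exp.counts[:, tech == "single_nucleus"].sum(axis=1)).ravel()
    n1, n2 = x1.sum(), x2.sum()
    keep = (x1 + x2) >= 30
    p1, p2 = x1[keep] / n1, x2[keep] / n2
    pp = (x1[keep] + x2[keep]) / (n1 + n2)
    z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
    assert abs(z.mean()) < 0.15
    assert 0.85 <= z.std() <= 1.15


def test_pooled_share_ranking_recovers_planted_bias():
    """Genes with the largest nucleus/cell pooled-share ratios have more
    exons than those with the smallest, in >= 95% of seeds."""
    hits = 0
    for seed in range(20):
        cat = simulate_gene_catalog(500, seed=seed)
        truth = SimulationTruth(seed=seed, n_genes=500, n_cells_per_technique=150,
                                bias_amplitude=4.0, mito_fraction=0.0, ribo_fraction=0.0)
        exp, _ = simulate_paired_experiment(cat, truth)
        tech = exp.technique_labels()
        x_nuc = np.asarray(exp.counts[:, tech == "single_nucleus"].sum(axis=1)).ravel()
        x_cell = np.asarray(exp.counts[:, tech == "single_cell"].sum(axis=1)).ravel()
        share_nuc = (x_nuc + 1) / (x_nuc.sum() + exp.n_genes)
        share_cell = (x_cell + 1) / (x_cell.sum() + exp.n_genes)
        ratio = share_nuc / share_cell
        exons = np.array([g.exon_count for g in exp.genes], dtype=float)
        order = np.argsort(ratio)
        hits += exons[order[-100:]].mean() > exons[order[:100]].mean()
    assert hits >= 19


def test_invalid_bias_amplitude_rejected(small_catalog):
    with pytest.raises(lb.InvalidArgumentError):
        SimulationTruth(bias_amplitude=0.99)
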