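"""Rank-sum test oracles, marker-scan filters, NB GLM behavior, list ops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import lenbias as lb
from lenbias.de import (
    find_technique_markers,
    marker_overlap,
    nb_glm_markers,
    top_n_markers,
    wilcoxon_rank_sum,
)
from lenbias.normalize import log_normalize
from lenbias.reference import wilcoxon_exact_reference
from lenbias.simulate import simulate_gene_catalog, simulate_paired_experiment
from lenbias.types import DEGRecord, MarkerFilter, SimulationTruth

from conftest import make_experiment


# ---------------------------------------------------------------- wilcoxon

def test_wilcoxon_separated_samples_exact_p():
    u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_identical_samples_p_one():
    assert wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])[1] == pytest.approx(1.0)
    assert wilcoxon_rank_sum([1, 1, 2], [1, 1, 2])[1] == pytest.approx(1.0)


def test_wilcoxon_tied_case_matches_enumeration():
    _, p = wilcoxon_rank_sum([1, 1, 2], [1, 2, 2], method="exact")
    _, p_ref = wilcoxon_exact_reference([1, 1, 2], [1, 2, 2])
    assert p == pytest.approx(p_ref, abs=1e-12)


@pytest.mark.parametrize("nx,ny", [(nx, ny) for nx in range(1, 6)
                                   for ny in range(nx, 11 - nx)])
def test_wilcoxon_exact_branch_matches_reference_all_partitions(nx, ny):
    """Exact branch equals full permutation enumeration for every split
    with pooled n <= 10, with and without ties."""
    rng = np.random.default_rng(nx * 100 + ny)
    for rep in range(3):
        x = rng.integers(0, 4, nx).astype(float)   # heavy ties
        y = rng.integers(0, 4, ny).astype(float)
        _, p = wilcoxon_rank_sum(x, y, method="exact")
        _, p_ref = wilcoxon_exact_reference(x, y)
        assert abs(p - p_ref) < 1e-10
    x = rng.normal(size=nx)
    y = rng.normal(size=ny)
    _, p = wilcoxon_rank_sum(x, y, method="exact")
    _, p_ref = wilcoxon_exact_reference(x, y)
    assert abs(p - p_ref) < 1e-10


def test_wilcoxon_asymptotic_close_to_enumeration_at_n12():
    rng = np.random.default_rng(12)
    for rep in range(50):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        _, pa = wilcoxon_rank_sum(x, y, method="asymptotic")
        _, pe = wilcoxon_rank_sum(x, y, method="exact")
        assert abs(pa - pe) <= 0.02


def test_wilcoxon_asymptotic_matches_scipy():
    rng = np.random.default_rng(5)
    x = rng.normal(size=40)
    y = rng.normal(0.4, 1.2, size=35)
    _, p = wilcoxon_rank_sum(x, y, method="asymptotic")
    assert p == pytest.approx(stats.mannwhitneyu(x, y, method="asymptotic").pvalue)


def test_wilcoxon_empty_input_rejected():
    with pytest.raises(lb.InvalidArgumentError):
        wilcoxon_rank_sum([], [1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(st.integers(0, 5), min_size=1, max_size=5),
    y=st.lists(st.integers(0, 5), min_size=1, max_size=5),
)
def test_wilcoxon_symmetry_and_range(x, y):
    """p is a probability and invariant under swapping the two samples."""
    _, pxy = wilcoxon_rank_sum(x, y)
    _, pyx = wilcoxon_rank_sum(y, x)
    assert 0.0 <= pxy <= 1.0
    assert pxy == pytest.approx(pyx, abs=1e-12)


# ---------------------------------------------------------- marker scan

def _norm_and_exp(counts, techniques):
    exp = make_experiment(np.asarray(counts), techniques=techniques)
    return log_normalize(exp), exp


def test_low_pct_gene_not_tested():
    # gene 0: expressed in 1/10 cells per group (pct 0.1) with a huge count;
    # gene 1: well expressed everywhere (keeps the scan nonempty)
    counts = np.zeros((2, 20), dtype=int)
    counts[0, 0] = 500
    counts[0, 10] = 50
    counts[1] = 10
    norm, exp = _norm_and_exp(counts, ["single_nucleus"] * 10 + ["single_cell"] * 10)
    recs = find_technique_markers(norm, exp, MarkerFilter(min_pct=0.25, logfc_threshold=0.0))
    assert "T0000" not in {r.gene_id for r in recs}


def test_small_logfc_gene_not_tested():
    # equal library size (50) everywhere so gene 0's fold change is exactly 0;
    # genes 1 and 2 are mirrored 8-fold markers
    counts = np.ones((3, 20), dtype=int) * 5
    counts[1, :10] = 40
    counts[2, :10] = 5
    counts[1, 10:] = 5
    counts[2, 10:] = 40
    norm, exp = _norm_and_exp(counts, ["single_nucleus"] * 10 + ["single_cell"] * 10)
    recs = find_technique_markers(norm, exp, MarkerFilter(min_pct=0.0, logfc_threshold=0.25))
    ids = {r.gene_id for r in recs}
    assert "T0000" not in ids and ids == {"T0001", "T0002"}


def test_planted_nucleus_gene_detected_with_positive_logfc():
    cat = simulate_gene_catalog(300, seed=13)
    planted = next(g.gene_id for g in cat if not (g.is_mito or g.is_ribo))
    truth = SimulationTruth(seed=13, n_genes=300, n_cells_per_technique=150,
                            bias_amplitude=1.0,
                            technique_fold_changes={planted: 4.0})
    exp, _ = simulate_paired_experiment(cat, truth)
    norm = log_normalize(exp)
    recs = find_technique_markers(norm, exp)
    rec = next(r for r in recs if r.gene_id == planted)
    assert rec.group == "single_nucleus"
    assert rec.log_fc > 0
    assert rec.p_adj < 0.05


def test_records_sorted_and_bonferroni_uses_tested_count():
    rng = np.random.default_rng(2)
    counts = rng.poisson(3, size=(30, 40))
    counts[:5, :20] *= 6
    norm, exp = _norm_and_exp(counts, ["single_nucleus"] * 20 + ["single_cell"] * 20)
    recs = find_technique_markers(norm, exp, MarkerFilter(min_pct=0.0, logfc_threshold=0.0))
    m = len(recs)
    for r in recs:
        assert r.p_adj == pytest.approx(min(1.0, r.p_value * m))
        assert r.p_adj >= r.p_value
        assert 0 <= r.pct_in <= 1 and 0 <= r.pct_out <= 1
    keys = [(r.p_adj, -abs(r.log_fc)) for r in recs]
    assert keys == sorted(keys)


# ---------------------------------------------------------------- NB GLM

def test_nb_glm_null_pvalues_uniform():
    cat = simulate_gene_catalog(300, seed=31)
    truth = SimulationTruth(seed=31, bias_amplitude=1.0, n_genes=300,
                            n_cells_per_technique=100)
    exp, _ = lb.null_experiment(cat, truth)
    recs = nb_glm_markers(exp, exp.technique_labels(),
                          MarkerFilter(min_pct=0.0, logfc_threshold=0.0),
                          labels=["single_nucleus"])
    ps = np.array([r.p_value for r in recs])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_nb_glm_permuted_labels_uniform(small_biased_run):
    exp, _ = small_biased_run
    rng = np.random.default_rng(0)
    fake = rng.permutation(exp.technique_labels())
    recs = nb_glm_markers(exp, fake, MarkerFilter(min_pct=0.05, logfc_threshold=0.0),
                          labels=["single_nucleus"])
    ps = np.array([r.p_value for r in recs])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_nb_glm_recovers_planted_fold_change():
    cat = simulate_gene_catalog(200, seed=17)
    planted = [g.gene_id for g in cat if not (g.is_mito or g.is_ribo)][:15]
    truth = SimulationTruth(seed=17, bias_amplitude=1.0, n_genes=200,
                            n_cells_per_technique=150,
                            technique_fold_changes={g: 4.0 for g in planted})
    exp, _ = simulate_paired_experiment(cat, truth)
    recs = nb_glm_markers(exp, exp.technique_labels(),
                          MarkerFilter(min_pct=0.0, logfc_threshold=0.0),
                          labels=["single_nucleus"])
    by_id = {r.gene_id: r for r in recs}
    power = np.mean([by_id[g].p_value < 0.05 for g in planted if g in by_id])
    assert power > 0.9
    betas = [by_id[g].log_fc for g in planted if g in by_id]
    assert np.median(betas) == pytest.approx(np.log(4.0), abs=0.4)


def test_nb_glm_survives_degenerate_gene():
    """An all-zero gene must not abort the scan; it is skipped or reported
    with p ~ 1, never with a spurious rejection."""
    rng = np.random.default_rng(4)
    counts = rng.poisson(2, size=(10, 60))
    counts[3, :] = 0
    exp = make_experiment(counts, techniques=["single_nucleus"] * 30 + ["single_cell"] * 30)
    recs = nb_glm_markers(exp, exp.technique_labels(),
                          MarkerFilter(min_pct=0.0, logfc_threshold=0.0),
                          labels=["single_nucleus"])
    degenerate = [r for r in recs if r.gene_id == "T0003"]
    assert len(recs) >= 8
    if degenerate:
        assert degenerate[0].p_value > 0.5


def test_nb_glm_group_size_guard():
    counts = np.ones((5, 10), dtype=int)
    exp = make_experiment(counts, techniques=["single_nucleus"] * 5 + ["single_cell"] * 5)
    with pytest.raises(lb.InvalidArgumentError, match="fewer than"):
        nb_glm_markers(exp, exp.technique_labels())


# ----------------------------------------------------------- list ops

def _rec(gene_id, symbol, group, log_fc, p=1e-4, padj=1e-3):
    return DEGRecord(gene_id, symbol, group, log_fc, p, padj, 0.9, 0.1)


def test_top_n_excludes_compartment_prefixes_from_cell_list():
    recs = [
        _rec("g1", "mt-Co1", "single_cell", 2.0),
        _rec("g2", "Rpl13", "single_cell", 1.8),
        _rec("g3", "Actb", "single_cell", 1.5),
        _rec("g4", "Ttn", "single_nucleus", 1.2),
        _rec("g5", "mt-Nd1", "single_nucleus", 1.1),
    ]
    tops = top_n_markers(recs, n=10)
    assert tops["single_cell"] == ["g3"]
    # exclusion applies to the whole-cell list only by default
    assert tops["single_nucleus"] == ["g4", "g5"]


def test_top_n_keeps_positive_direction_and_warns_when_short(caplog):
    recs = [
        _rec("g1", "A", "single_cell", 1.0),
        _rec("g2", "B", "single_cell", -0.5),
    ]
    import logging

    with caplog.at_level(logging.WARNING, logger="lenbias.de"):
        tops = top_n_markers(recs, n=5)
    assert tops["single_cell"] == ["g1"]
    assert any("only 1 markers available" in r.message for r in caplog.records)


def test_marker_overlap_arithmetic():
    rep = marker_overlap(list("abcd"), list("cdef"))
    assert rep["n_intersection"] == 2
    assert rep["n_union"] == 6
    assert rep["shared_fraction"] == pytest.approx(2 / 6)
    assert marker_overlap(["x"], ["x"])["shared_fraction"] == 1.0
    assert marker_overlap(["x"], ["y"])["shared_fraction"] == 0.0
    with pytest.raises(lb.InvalidArgumentError):
        marker_overlap([], ["a"])
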