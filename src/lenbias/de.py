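"""Differential expression between techniques or clusters.

Two tests are provided:

* :func:`wilcoxon_rank_sum` — a two-sample rank-sum test with midranks
  for ties.  For small pooled samples (n_x + n_y <= 12) the two-sided
  p-value is computed exactly by enumerating all label assignments of the
  pooled midranks; otherwise the normal approximation with tie correction
  and a 0.5 continuity correction is used.
* :func:`nb_glm_markers` — a per-gene negative-binomial GLM of raw counts
  on a group indicator with a log library-size offset; the dispersion is
  estimated once by method of moments on the full-model fit and the
  p-value comes from a likelihood-ratio chi-square test with 1 df.

Marker scans apply the conventional filters: a gene is tested only if
expressed in at least ``min_pct`` of the cells of one group and if its
natural-log fold change (on expm1-ed normalized means with pseudocount 1)
exceeds ``logfc_threshold``.  P-values are Bonferroni-corrected over the
genes actually tested.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .normalize import NormalizedMatrix
from .types import (
    DEGRecord,
    InvalidArgumentError,
    MarkerFilter,
    PairedExperiment,
)

logger = logging.getLogger(__name__)

EXACT_LIMIT = 12  # pooled size at or below which the exact branch runs


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test (Mann-Whitney U form).

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    ``method`` is ``'auto'`` (exact when n_x + n_y <= 12), ``'exact'`` or
    ``'asymptotic'``.  The exact branch enumerates every assignment of the
    pooled midranks to the two labels, so it is valid with ties; its
    two-sided p-value is the fraction of assignments at least as extreme
    (|U - n_x n_y / 2|) as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both samples must be nonempty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_x = ranks[:nx].sum()
    u_x = w_x - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0

    if method == "auto":
        method = "exact" if n <= EXACT_LIMIT else "asymptotic"
    if method == "exact":
        obs = abs(u_x - mu)
        hits = 0
        total = 0
        min_rank_sum = 0.0
        for idx in combinations(range(n), nx):
            w = ranks[list(idx)].sum()
            u = w - nx * (nx + 1) / 2.0
            if abs(u - mu) >= obs - 1e-12:
                hits += 1
            total += 1
        return float(u_x), hits / total
    if method != "asymptotic":
        raise InvalidArgumentError(f"unknown method {method!r}")

    # normal approximation, tie-corrected variance, continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return float(u_x), 1.0
    num = abs(u_x - mu) - 0.5
    z = max(num, 0.0) / math.sqrt(var)
    return float(u_x), float(2.0 * stats.norm.sf(z))


def _log_fc(mean_in: float, mean_out: float) -> float:
    """Natural-log fold change on expm1-ed means with pseudocount 1."""
    return math.log(mean_in + 1.0) - math.log(mean_out + 1.0)


def _group_stats(
    values: sp.csc_matrix, mask: np.ndarray, undo_log: bool
) -> tuple[np.ndarray, np.ndarray]:
    """(pct expressing, mean expression) per gene for one cell group.

    With ``undo_log`` the mean is taken on expm1-ed values (the log-scale
    convention); otherwise on the values as given.
    """
    sub = sp.csr_matrix(values[:, mask])
    n = int(mask.sum())
    pct = sub.getnnz(axis=1) / n
    lin = sub.copy()
    if undo_log:
        lin.data = np.expm1(lin.data)
    means = np.asarray(lin.sum(axis=1)).ravel() / n
    return pct, means


def find_technique_markers(
    norm: NormalizedMatrix,
    exp: PairedExperiment,
    flt: MarkerFilter = MarkerFilter(),
    group_1: str = "single_nucleus",
    group_2: str = "single_cell",
) -> list[DEGRecord]:
    """Between-technique marker scan on normalized values.

    Each tested gene yields one record oriented toward the technique with
    the higher expm1-mean (log_fc > 0 in that group). Bonferroni
    correction uses the number of genes that passed both prefilters.
    Records are sorted by (p_adj ascending, |log_fc| descending).
    """
    techs = exp.technique_labels()
    m1 = techs == group_1
    m2 = techs == group_2
    if not m1.any() or not m2.any():
        raise InvalidArgumentError(f"both groups {group_1!r}/{group_2!r} must be present")

    undo_log = norm.method == "log_scaled"
    pct1, mean1 = _group_stats(norm.values, m1, undo_log)
    pct2, mean2 = _group_stats(norm.values, m2, undo_log)
    lfc = np.log(mean1 + 1.0) - np.log(mean2 + 1.0)
    tested = np.nonzero(
        (np.maximum(pct1, pct2) >= flt.min_pct) & (np.abs(lfc) >= flt.logfc_threshold)
    )[0]

    dense = np.asarray(norm.values[tested, :].todense()) if tested.size else np.empty((0, exp.n_cells))
    pvals = np.empty(tested.size)
    for k in range(tested.size):
        row = dense[k]
        _, pvals[k] = wilcoxon_rank_sum(row[m1], row[m2], method="asymptotic")
    m = tested.size
    padj = np.minimum(1.0, pvals * m)

    records = []
    for k, g in enumerate(tested):
        gene = exp.genes[g]
        if lfc[g] >= 0:
            grp, fc, pi, po = group_1, lfc[g], pct1[g], pct2[g]
        else:
            grp, fc, pi, po = group_2, -lfc[g], pct2[g], pct1[g]
        records.append(
            DEGRecord(gene.gene_id, gene.symbol, grp, float(fc), float(pvals[k]),
                      float(padj[k]), float(pi), float(po))
        )
    records.sort(key=lambda r: (r.p_adj, -abs(r.log_fc), r.gene_id))
    return records


# --------------------------------------------------------------------------
# negative-binomial GLM test
# --------------------------------------------------------------------------

def _nb_theta_mom(y: np.ndarray, mu: np.ndarray, floor: float = 0.01) -> float:
    """Method-of-moments NB size estimate from a fitted mean vector.

    Solves sum((y-mu)^2 - mu) = sum(mu^2)/theta; a non-positive excess
    (under-dispersion) maps to a near-Poisson theta.
    """
    excess = float(((y - mu) ** 2 - mu).sum())
    if excess <= 0:
        return 1e8
    return max(float((mu**2).sum()) / excess, floor)


def _nb_glm_gene(
    y: np.ndarray, group: np.ndarray, offset: np.ndarray
) -> tuple[float, float]:
    """(log_fc estimate, LRT p) for one gene; raises on non-convergence."""
    import statsmodels.api as sm

    x_full = np.column_stack([np.ones_like(offset), group.astype(float)])
    x_null = x_full[:, :1]
    pois = sm.GLM(y, x_full, family=sm.families.Poisson(), offset=offset).fit()
    theta = _nb_theta_mom(y, pois.mu)
    fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
    full = sm.GLM(y, x_full, family=fam, offset=offset).fit()
    null = sm.GLM(y, x_null, family=fam, offset=offset).fit()
    lr = 2.0 * (full.llf - null.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return float(full.params[1]), p


def nb_glm_markers(
    exp: PairedExperiment,
    groups: np.ndarray,
    flt: MarkerFilter = MarkerFilter(),
    min_cells_per_group: int = 20,
    labels: list | None = None,
) -> list[DEGRecord]:
    """One-vs-rest NB GLM marker scan on raw counts.

    For every group label (restrictable via ``labels``; with exactly two
    groups the two scans are mirror images), each prefiltered gene is
    regressed on the in-group indicator with a log total-count offset.
    Genes whose fit fails are logged and skipped. Bonferroni correction is
    per-scan over the tested genes of that group.
    """
    groups = np.asarray(groups)
    all_labels = sorted(set(groups.tolist()))
    if len(all_labels) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    if labels is None:
        labels = all_labels
    elif set(labels) - set(all_labels):
        raise InvalidArgumentError(f"unknown group labels {sorted(set(labels) - set(all_labels))}")
    for lab in all_labels:
        if (groups == lab).sum() < min_cells_per_group:
            raise InvalidArgumentError(
                f"group {lab!r} has fewer than {min_cells_per_group} cells"
            )
    totals = exp.total_counts().astype(float)
    offset = np.log(totals)
    counts = sp.csr_matrix(exp.counts)

    records: list[DEGRecord] = []
    for lab in labels:
        mask = groups == lab
        pct_in = counts[:, mask].getnnz(axis=1) / mask.sum()
        pct_out = counts[:, ~mask].getnnz(axis=1) / (~mask).sum()
        # log-FC prefilter on depth-normalized means (pseudocount 1 per 1e4)
        mean_in = np.asarray(counts[:, mask].sum(axis=1)).ravel() / totals[mask].sum() * 1e4
        mean_out = np.asarray(counts[:, ~mask].sum(axis=1)).ravel() / totals[~mask].sum() * 1e4
        lfc0 = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
        tested = np.nonzero(
            (np.maximum(pct_in, pct_out) >= flt.min_pct)
            & (np.abs(lfc0) >= flt.logfc_threshold)
        )[0]

        results = []
        for g in tested:
            y = np.asarray(counts[g, :].todense()).ravel()
            try:
                beta, p = _nb_glm_gene(y, mask, offset)
            except Exception as e:
                logger.warning("NB GLM failed for gene %s (%s); skipped",
                               exp.genes[g].gene_id, e)
                continue
            results.append((g, beta, p))
        m = len(results)
        for g, beta, p in results:
            gene = exp.genes[g]
            records.append(
                DEGRecord(gene.gene_id, gene.symbol, str(lab), beta, p,
                          min(1.0, p * m), float(pct_in[g]), float(pct_out[g]))
            )
    records.sort(key=lambda r: (r.group, r.p_adj, -abs(r.log_fc), r.gene_id))
    return records


def top_n_markers(
    records: list[DEGRecord],
    n: int = 100,
    flt: MarkerFilter = MarkerFilter(),
    exclude_groups: tuple[str, ...] = ("single_cell",),
) -> dict[str, list[str]]:
    """Top-n positive markers per group, after prefix exclusion.

    Mitochondrial/ribosomal symbol prefixes are removed from the listed
    ``exclude_groups`` (by default the whole-cell list only, since nuclei
    never capture those genes; pass all groups to exclude everywhere).
    Emits a warning when fewer than ``n`` markers survive.
    """
    out: dict[str, list[str]] = {}
    groups = sorted({r.group for r in records})
    for grp in groups:
        rows = [r for r in records if r.group == grp]
        if flt.positive_only:
            rows = [r for r in rows if r.log_fc > 0]
        if grp in exclude_groups or "__all__" in exclude_groups:
            rows = [
                r for r in rows
                if not any(r.symbol.startswith(p) for p in flt.exclude_prefixes)
            ]
        if len(rows) < n:
            logger.warning("group %s: only %d markers available (requested %d)",
                           grp, len(rows), n)
        out[grp] = [r.gene_id for r in rows[:n]]
    return out


def marker_overlap(list_a: list[str], list_b: list[str]) -> dict[str, float]:
    """Set overlap of two marker lists; shared fraction uses the union size."""
    if not list_a or not list_b:
        raise InvalidArgumentError("marker lists must be nonempty")
    a, b = set(list_a), set(list_b)
    inter = a & b
    union = a | b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(inter),
        "n_union": len(union),
        "shared_fraction": len(inter) / len(union),
    }


def records_to_frame(records: list[DEGRecord]):
    """DEG table as a DataFrame (the TSV a volcano plot would consume)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "symbol": r.symbol,
                "group": r.group,
                "log_fc": r.log_fc,
                "p_value": r.p_value,
                "p_adj": r.p_adj,
                "pct_in": r.pct_in,
                "pct_out": r.pct_out,
            }
            for r in records
        ]
    )
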