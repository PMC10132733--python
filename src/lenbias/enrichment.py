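"""Per-cell single-sample gene-set enrichment (ssGSEA-style).

For each cell, genes are ranked by normalized expression (descending,
midranks for ties, index-stable order within a tie group).  Walking the
ranked list, the enrichment score is the summed gap between the weighted
cumulative fraction of set members seen so far (weights = ascending
midrank position raised to ``alpha``, so the score is a pure rank
statistic) and the unweighted cumulative fraction of non-members:

    ES = sum_i [ P_in(i) - P_out(i) ],  i = 1..N

Normalized scores divide each cell's ES by the range of ES over all
scored cells, so the population spans an interval of width 1; the
between-technique comparison is a rank-sum test on the NES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .de import wilcoxon_rank_sum
from .normalize import NormalizedMatrix
from .types import GeneSet, InvalidArgumentError, PairedExperiment

logger = logging.getLogger(__name__)


def ssgsea_score(expression: np.ndarray, in_set: np.ndarray, alpha: float = 0.25) -> float:
    """Enrichment score of one cell for one gene set.

    ``expression`` is the cell's normalized expression over all N measured
    genes; ``in_set`` a boolean membership mask. The set must be a proper
    nonempty subset of the measured genes.
    """
    expression = np.asarray(expression, dtype=float)
    in_set = np.asarray(in_set, dtype=bool)
    if expression.shape != in_set.shape:
        raise InvalidArgumentError("expression and membership mask must align")
    n = expression.size
    k = int(in_set.sum())
    if k == 0:
        raise InvalidArgumentError("gene set has no measured members")
    if k >= n:
        raise InvalidArgumentError("gene set covers all measured genes; P_out undefined")

    # ascending midranks -> weight; stable descending walk order
    asc_rank = stats.rankdata(expression)           # midranks, 1 = lowest
    weights = asc_rank**alpha
    order = np.argsort(-expression, kind="stable")
    w_ord = weights[order] * in_set[order]
    out_ord = (~in_set[order]).astype(float)
    p_in = np.cumsum(w_ord) / w_ord.sum()
    p_out = np.cumsum(out_ord) / (n - k)
    return float((p_in - p_out).sum())


@dataclass
class EnrichmentResult:
    """Per-cell ES/NES for one gene set and the between-technique test."""

    set_name: str
    cell_ids: list[str]
    techniques: list[str]
    es: np.ndarray
    nes: np.ndarray
    statistic: float
    p_value: float
    n_dropped_genes: int

    def mean_nes(self, technique: str) -> float:
        mask = np.array(self.techniques) == technique
        return float(self.nes[mask].mean())


def score_experiment(
    norm: NormalizedMatrix,
    exp: PairedExperiment,
    gene_set: GeneSet,
    alpha: float = 0.25,
) -> EnrichmentResult:
    """Score every cell and compare NES between the two techniques.

    Set members absent from the expression matrix are dropped (logged).
    NES = ES / (max ES - min ES) over all scored cells.
    """
    techs = exp.technique_labels()
    for tech in np.unique(techs):
        if (techs == tech).sum() < 2:
            raise InvalidArgumentError(f"technique {tech!r} has fewer than 2 cells")
    gene_ids = exp.gene_ids
    in_set = np.array([g in gene_set.members for g in gene_ids])
    dropped = len(gene_set.members) - int(in_set.sum())
    if dropped:
        logger.info("gene set %s: %d member(s) not measured, dropped",
                    gene_set.name, dropped)
    dense = np.asarray(norm.values.todense())
    es = np.empty(exp.n_cells)
    for j in range(exp.n_cells):
        es[j] = ssgsea_score(dense[:, j], in_set, alpha=alpha)
    rng_width = es.max() - es.min()
    if rng_width == 0:
        raise InvalidArgumentError("all cells share one ES; NES normalization degenerate")
    nes = es / rng_width
    labels = sorted(np.unique(techs))
    stat, p = wilcoxon_rank_sum(nes[techs == labels[0]], nes[techs == labels[1]],
                                method="asymptotic")
    return EnrichmentResult(
        set_name=gene_set.name,
        cell_ids=[c.cell_id for c in exp.cells],
        techniques=techs.tolist(),
        es=es, nes=nes, statistic=stat, p_value=p,
        n_dropped_genes=dropped,
    )


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InvalidArgumentError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *members = parts
        sets[name] = GeneSet(name, frozenset(m for m in members if m))
    if not sets:
        raise InvalidArgumentError(f"{path}: no gene sets found")
    return sets
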