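"""Depth-matched balanced subsampling.

Between-technique comparisons are confounded by sequencing depth, so the
pipeline restricts cells to a per-technique library-size window in which
genes-per-cell grows linearly with counts-per-cell, then draws an equal
number of cells per technique uniformly without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import (
    TECHNIQUES,
    DepthWindow,
    InsufficientDataError,
    PairedExperiment,
)


@dataclass(frozen=True)
class LinearityReport:
    """Pearson correlation between depth and detected genes, per technique."""

    pearson_r: dict[str, float]
    n_cells: dict[str, int]
    threshold: float

    @property
    def passed(self) -> dict[str, bool]:
        return {t: r >= self.threshold for t, r in self.pearson_r.items()}


def linearity_check(
    exp: PairedExperiment,
    window: DepthWindow,
    threshold: float = 0.6,
    min_cells: int = 10,
) -> LinearityReport:
    """Advisory diagnostic: within the window, are counts and features linear?"""
    totals = exp.total_counts()
    feats = exp.n_features()
    techs = exp.technique_labels()
    in_window = window.mask(totals, techs)
    rs: dict[str, float] = {}
    ns: dict[str, int] = {}
    for tech in window.bounds:
        sel = in_window & (techs == tech)
        n = int(sel.sum())
        if n < min_cells:
            raise InsufficientDataError(
                f"{tech}: only {n} cells inside the depth window (need >= {min_cells})"
            )
        x = totals[sel].astype(float)
        y = feats[sel].astype(float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            raise InsufficientDataError(
                f"{tech}: no variation in counts/features inside the window; r undefined"
            )
        rs[tech] = float(stats.pearsonr(x, y).statistic)
        ns[tech] = n
    return LinearityReport(rs, ns, threshold)


def balanced_subsample(
    exp: PairedExperiment,
    window: DepthWindow,
    n_per_technique: int = 1000,
    seed: int = 0,
) -> PairedExperiment:
    """Uniform, seeded, without-replacement draw of n cells per technique
    from inside the depth window. Gene order is preserved."""
    totals = exp.total_counts()
    techs = exp.technique_labels()
    in_window = window.mask(totals, techs)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for tech in sorted(window.bounds):
        pool = np.nonzero(in_window & (techs == tech))[0]
        if pool.size < n_per_technique:
            raise InsufficientDataError(
                f"{tech}: {pool.size} cells inside the window, need {n_per_technique}"
            )
        chosen.append(rng.choice(pool, size=n_per_technique, replace=False))
    cell_idx = np.sort(np.concatenate(chosen))
    return exp.subset(cell_idx=cell_idx)
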