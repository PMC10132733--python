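"""Structural annotation of gene lists and length/exon-count bias statistics.

Given two top-marker lists (one per technique) and the per-gene structure
catalog, this module quantifies how the lists differ in exon count,
transcript length, CDS length and genomic span — pairwise (list vs list)
and against the host-genome background (list vs whole catalog) — with
rank-sum tests, sample skewness, density-curve data and a binned
exon-count table with a chi-square goodness-of-fit statistic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import wilcoxon_rank_sum
from .types import (
    STRUCTURE_FEATURES,
    GeneStructure,
    InsufficientDataError,
    InvalidArgumentError,
    catalog_to_frame,
)

logger = logging.getLogger(__name__)


def annotate_list(
    gene_ids: Sequence[str],
    catalog: Sequence[GeneStructure] | pd.DataFrame,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Look up structural annotation for a gene list.

    Returns ``(table, remainder)``: one row per annotated input gene and
    the ids missing from the catalog. Duplicate ids are dropped with a
    warning. In strict mode, more than 20% unannotated genes is an error.
    """
    frame = catalog if isinstance(catalog, pd.DataFrame) else catalog_to_frame(catalog)
    ids = list(gene_ids)
    seen: set[str] = set()
    unique_ids = []
    for gid in ids:
        if gid in seen:
            continue
        seen.add(gid)
        unique_ids.append(gid)
    if len(unique_ids) < len(ids):
        logger.warning("annotate_list: %d duplicate ids removed", len(ids) - len(unique_ids))
    present = [g for g in unique_ids if g in frame.index]
    remainder = [g for g in unique_ids if g not in frame.index]
    if unique_ids and len(remainder) / len(unique_ids) > 0.2:
        msg = f"{len(remainder)}/{len(unique_ids)} genes missing from the annotation catalog"
        if strict:
            raise InvalidArgumentError(msg)
        logger.warning("annotate_list: %s", msg)
    return frame.loc[present].copy(), remainder


def sample_skewness(values: Sequence[float]) -> float:
    """Fisher-Pearson sample skewness g1 = m3 / m2^(3/2) (moment estimators)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InvalidArgumentError("skewness needs at least 3 values")
    if np.ptp(v) == 0:
        raise InvalidArgumentError("skewness undefined for zero-variance data")
    return float(stats.skew(v, bias=True))


@dataclass
class FeatureComparison:
    """One structural feature compared between two gene lists."""

    feature: str
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    skewness_a: float
    skewness_b: float
    statistic: float
    p_value: float


@dataclass
class ExonBinTable:
    """Observed vs genome-expected fractions of genes per exon-count bin."""

    edges: list[float]
    labels: list[str]
    observed: dict[str, list[float]]
    expected: list[float]
    chi2: dict[str, float]
    chi2_p: dict[str, float]

    def check(self) -> None:
        for name, obs in self.observed.items():
            if abs(sum(obs) - 1.0) > 1e-9:
                raise InvalidArgumentError(f"{name}: observed fractions sum != 1")
        if abs(sum(self.expected) - 1.0) > 1e-9:
            raise InvalidArgumentError("expected fractions sum != 1")


@dataclass
class BiasReport:
    """Structural-bias summary for one or two gene lists.

    ``pairwise`` holds list-vs-list comparisons, ``background`` list-vs-
    genome comparisons keyed by list name, ``exon_bins`` the binned
    exon-count distribution against the genome expectation, and
    ``density`` exon-count density-curve data per list.
    """

    list_names: list[str]
    pairwise: list[FeatureComparison] = field(default_factory=list)
    background: dict[str, list[FeatureComparison]] = field(default_factory=dict)
    exon_bins: ExonBinTable | None = None
    density: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "BiasReport":
        d = json.loads(text)
        rep = BiasReport(list_names=d["list_names"])
        rep.pairwise = [FeatureComparison(**fc) for fc in d["pairwise"]]
        rep.background = {
            k: [FeatureComparison(**fc) for fc in v] for k, v in d["background"].items()
        }
        if d.get("exon_bins") is not None:
            rep.exon_bins = ExonBinTable(**d["exon_bins"])
        rep.density = d.get("density", {})
        return rep

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @staticmethod
    def load(path: str | Path) -> "BiasReport":
        return BiasReport.from_json(Path(path).read_text())


def _compare_feature(name: str, a: np.ndarray, b: np.ndarray) -> FeatureComparison:
    stat, p = wilcoxon_rank_sum(a, b)
    def g1(v: np.ndarray) -> float:
        return sample_skewness(v) if np.ptp(v) > 0 and v.size >= 3 else float("nan")
    return FeatureComparison(
        feature=name,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        skewness_a=g1(a), skewness_b=g1(b),
        statistic=stat, p_value=p,
    )


def _exon_density(values: np.ndarray, grid_max: int = 80) -> dict[str, list[float]]:
    """Gaussian-KDE density of exon counts on an integer grid, plus the mean."""
    grid = np.arange(1, grid_max + 1, dtype=float)
    if np.ptp(values) == 0:
        dens = (grid == values[0]).astype(float)
    else:
        dens = stats.gaussian_kde(values.astype(float))(grid)
    return {"grid": grid.tolist(), "density": dens.tolist(), "mean": [float(values.mean())]}


def compare_structures(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    name_a: str = "list_a",
    name_b: str = "list_b",
    features: Sequence[str] = STRUCTURE_FEATURES,
) -> BiasReport:
    """Pairwise structural comparison of two annotated gene lists."""
    if table_a.empty or table_b.empty:
        raise InvalidArgumentError("both annotation tables must be nonempty")
    rep = BiasReport(list_names=[name_a, name_b])
    for feat in features:
        a = table_a[feat].to_numpy(dtype=float)
        b = table_b[feat].to_numpy(dtype=float)
        rep.pairwise.append(_compare_feature(feat, a, b))
    rep.density = {
        name_a: _exon_density(table_a["exon_count"].to_numpy()),
        name_b: _exon_density(table_b["exon_count"].to_numpy()),
    }
    return rep


def default_exon_bin_edges(max_unit: int = 70) -> list[float]:
    """Unit bins 1..max_unit plus one open-ended bin above."""
    return [*range(1, max_unit + 2), float("inf")]


def exon_bin_table(
    tables: dict[str, pd.DataFrame],
    catalog_frame: pd.DataFrame,
    edges: Sequence[float] | None = None,
) -> ExonBinTable:
    """Observed per-list exon-count bin fractions vs the genome expectation.

    ``edges`` are ascending left-closed bin edges (last may be inf). The
    chi-square statistic compares each list's observed bin counts with the
    genome fractions scaled to the list size; bins are as given, so with
    unit default bins and small lists the chi-square is descriptive
    (choose coarser edges for a calibrated test).
    """
    edges = list(edges) if edges is not None else default_exon_bin_edges()
    if sorted(edges) != edges or len(edges) < 2:
        raise InvalidArgumentError("bin edges must be ascending with >= 2 entries")
    arr_edges = np.asarray(edges, dtype=float)
    labels = [
        f"{int(arr_edges[i])}+" if np.isinf(arr_edges[i + 1]) else
        (f"{int(arr_edges[i])}" if arr_edges[i + 1] - arr_edges[i] == 1
         else f"{int(arr_edges[i])}-{int(arr_edges[i + 1]) - 1}")
        for i in range(len(arr_edges) - 1)
    ]

    genome = catalog_frame["exon_count"].to_numpy(dtype=float)
    exp_counts, _ = np.histogram(genome, bins=arr_edges)
    if exp_counts.sum() != genome.size:
        raise InvalidArgumentError("bin edges do not cover the genome exon-count range")
    expected = exp_counts / exp_counts.sum()

    observed: dict[str, list[float]] = {}
    chi2: dict[str, float] = {}
    chi2_p: dict[str, float] = {}
    for name, table in tables.items():
        vals = table["exon_count"].to_numpy(dtype=float)
        obs_counts, _ = np.histogram(vals, bins=arr_edges)
        if obs_counts.sum() != vals.size:
            raise InvalidArgumentError(f"{name}: values fall outside the bin edges")
        observed[name] = (obs_counts / obs_counts.sum()).tolist()
        keep = expected > 0
        exp_scaled = expected[keep] / expected[keep].sum() * obs_counts.sum()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c2, p = stats.chisquare(obs_counts[keep], exp_scaled)
        chi2[name] = float(c2)
        chi2_p[name] = float(p)
    table = ExonBinTable(
        edges=[float(e) for e in arr_edges], labels=labels,
        observed=observed, expected=expected.tolist(), chi2=chi2, chi2_p=chi2_p,
    )
    table.check()
    return table


def genome_background_comparison(
    table: pd.DataFrame,
    catalog: Sequence[GeneStructure] | pd.DataFrame,
    name: str = "list",
    features: Sequence[str] = STRUCTURE_FEATURES,
    edges: Sequence[float] | None = None,
    exclude_list_from_background: bool = False,
    min_catalog_ratio: float = 10.0,
) -> BiasReport:
    """Compare one annotated list against the whole-genome catalog.

    Per feature: a rank-sum test of list values vs all catalog values and
    skewness for both; plus the binned exon-count table with chi-square.
    """
    frame = catalog if isinstance(catalog, pd.DataFrame) else catalog_to_frame(catalog)
    if table.empty:
        raise InvalidArgumentError("annotation table must be nonempty")
    if len(frame) < min_catalog_ratio * len(table):
        raise InsufficientDataError(
            f"catalog ({len(frame)}) must be >= {min_catalog_ratio}x the list size ({len(table)})"
        )
    background = frame.drop(index=table.index, errors="ignore") if exclude_list_from_background else frame
    rep = BiasReport(list_names=[name, "genome"])
    comps = []
    for feat in features:
        comps.append(
            _compare_feature(
                feat,
                table[feat].to_numpy(dtype=float),
                background[feat].to_numpy(dtype=float),
            )
        )
    rep.background[name] = comps
    rep.exon_bins = exon_bin_table({name: table}, background, edges=edges)
    rep.density = {name: _exon_density(table["exon_count"].to_numpy())}
    return rep


def density_frame(report: BiasReport) -> pd.DataFrame:
    """Plot-ready long-format exon-count density curves (TSV export)."""
    rows = []
    for name, d in report.density.items():
        for g, y in zip(d["grid"], d["density"]):
            rows.append({"list": name, "exon_count": g, "density": y, "mean": d["mean"][0]})
    return pd.DataFrame(rows)
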