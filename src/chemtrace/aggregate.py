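"""Ontology-aware intensity aggregation, rankings, prevalence and
clustered fluorinated-feature matrices.

Samples carry hierarchical food-ontology labels (level 1: plant / animal
/ algal / fungal product; level 2: finer groups such as dairy). The
operations here aggregate the long-format measurement table over those
groups for selected feature subsets, rank a compound's food sources,
compute detection prevalence within a population, and build the clustered
matrix of top fluorinated putative xenobiotics per group.

Aggregation semantics: a *block* is the set of (feature, sample) cells
for one feature subset crossed with one sample group. ``mean`` is the
arithmetic mean over all cells of the block including non-detect zeros
(the matrix is dense post-normalization); ``sum`` is the block total. The
optional log transform, log10(x+1), is applied after aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .xenobiotics import PUTATIVE_XENOBIOTIC, XenobioticCall, round_half_up

__all__ = [
    "AggMatrix",
    "to_long",
    "aggregate_by_group",
    "top_sources",
    "prevalence",
    "top_fluorinated_matrix",
]

FOODON_LEVELS = ("foodon_l1", "foodon_l2", "food_name")


@dataclass
class AggMatrix:
    """Aggregated intensity matrix with its provenance.

    ``values`` rows are groups or features, columns are subsets or
    groups, depending on the producing operation. ``row_order`` and
    ``col_order`` hold dendrogram leaf orders when clustering was
    applied, else the plain label order.
    """

    values: pd.DataFrame
    aggregation: str
    transform: str = "none"
    row_order: list[str] = field(default_factory=list)
    col_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_order:
            self.row_order = list(self.values.index)
        if not self.col_order:
            self.col_order = list(self.values.columns)


def to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a features × samples matrix into (feature_id, sample_id, intensity).

    Row count is exactly #features × #samples; values are preserved.
    Duplicate feature or sample labels are rejected.
    """
    if wide.index.has_duplicates:
        dups = wide.index[wide.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups[:10]}")
    if wide.columns.has_duplicates:
        dups = wide.columns[wide.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:10]}")
    long = wide.rename_axis(index="feature_id", columns="sample_id").stack().reset_index()
    long.columns = ["feature_id", "sample_id", "intensity"]
    return long


def _apply_transform(values: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "none":
        return values
    if transform == "log10p1":
        return np.log10(values + 1.0)
    raise ValueError(f"unknown transform {transform!r}")


def aggregate_by_group(
    long: pd.DataFrame,
    metadata: pd.DataFrame,
    group_by: str,
    feature_subsets: Mapping[str, Collection[str]],
    aggregation: str = "mean",
    transform: str = "none",
) -> AggMatrix:
    """Aggregate intensities per (sample group × feature subset) block.

    ``group_by`` is a metadata column (one of the food-ontology levels).
    ``feature_subsets`` maps a subset label (e.g. a source database or a
    therapeutic category) to its feature ids; subsets may overlap. Empty
    subsets yield structurally-present zero columns.
    """
    if group_by not in metadata.columns:
        raise ValueError(f"metadata has no column {group_by!r}")
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    merged = long.merge(metadata[["sample_id", group_by]], on="sample_id", how="left")
    groups = sorted(metadata[group_by].dropna().unique())
    out = pd.DataFrame(0.0, index=groups, columns=list(feature_subsets))
    for label, ids in feature_subsets.items():
        ids = set(ids)
        block = merged[merged["feature_id"].isin(ids)]
        if block.empty:
            continue
        agg = block.groupby(group_by)["intensity"].agg(aggregation)
        out[label] = agg.reindex(groups).fillna(0.0)
    out = _apply_transform(out, transform)
    return AggMatrix(values=out, aggregation=aggregation, transform=transform)


def top_sources(
    long: pd.DataFrame,
    metadata: pd.DataFrame,
    feature_id: str,
    n: int = 10,
) -> pd.DataFrame:
    """Top food sources of one feature by per-food mean intensity.

    Means are taken over each food's samples (replicates average within
    the food). Foods where the feature is entirely absent are dropped, so
    the ranking has *up to* ``n`` rows. Ties order alphabetically by food
    name. Columns: food_name, mean_intensity.
    """
    sub = long[long["feature_id"] == feature_id]
    if sub.empty:
        raise KeyError(f"feature {feature_id!r} not present in the long table")
    merged = sub.merge(metadata[["sample_id", "food_name"]], on="sample_id", how="left")
    means = merged.groupby("food_name")["intensity"].mean()
    means = means[means > 0]
    ranked = means.reset_index().rename(columns={"intensity": "mean_intensity"})
    ranked = ranked.sort_values(
        ["mean_intensity", "food_name"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(n).reset_index(drop=True)


def prevalence(
    long: pd.DataFrame,
    metadata: pd.DataFrame,
    feature_id: str,
    population: Optional[str] = None,
    detect_min: float = 0.0,
) -> tuple[int, int, int]:
    """Detection prevalence of a feature within a sample population.

    ``population`` selects samples by ``foodon_l1`` (``None`` = all
    samples). Returns (k detections, n samples, percent) with the percent
    rounded half-up to an integer — 63 of 65 gives 97.
    """
    if population is None:
        samples = metadata["sample_id"]
    else:
        samples = metadata.loc[metadata["foodon_l1"] == population, "sample_id"]
    samples = set(samples)
    if not samples:
        raise ValueError(f"empty population {population!r}")
    sub = long[(long["feature_id"] == feature_id) & long["sample_id"].isin(samples)]
    k = int((sub["intensity"] > detect_min).sum())
    n = len(samples)
    return k, n, int(round_half_up(100.0 * k / n))


def _leaf_order(matrix: np.ndarray, labels: list[str]) -> list[str]:
    """Deterministic average-linkage/Euclidean dendrogram leaf order.

    Labels are pre-sorted so that identical inputs give identical orders
    regardless of incoming label order; fewer than three items keep the
    sorted order.
    """
    if len(labels) < 3:
        return labels
    dist = pdist(matrix, metric="euclidean")
    order = leaves_list(linkage(dist, method="average"))
    return [labels[i] for i in order]


def top_fluorinated_matrix(
    calls: Iterable[XenobioticCall],
    long: pd.DataFrame,
    metadata: pd.DataFrame,
    level: str = "foodon_l1",
    k: int = 10,
    transform: str = "log10p1",
) -> AggMatrix:
    """Clustered matrix of top fluorinated putative xenobiotics per group.

    For each sample group at the chosen ontology level, the ``k``
    fluorinated xenobiotic features with the highest within-group mean
    intensity are selected; the union of those selections defines the
    rows (a feature topping two groups appears once). Cells hold the
    transformed per-group mean. Rows and columns are ordered by
    average-linkage hierarchical clustering on Euclidean distances of the
    transformed matrix, with label-sorted input for deterministic leaf
    orders.
    """
    if level not in FOODON_LEVELS:
        raise ValueError(f"level must be one of {FOODON_LEVELS}, got {level!r}")
    fluor_ids = sorted(
        {c.feature_id for c in calls if c.call == PUTATIVE_XENOBIOTIC and c.fluorinated}
    )
    groups = sorted(metadata[level].dropna().unique())
    if not fluor_ids:
        empty = pd.DataFrame(index=pd.Index([], name="feature_id"), columns=groups, dtype=float)
        return AggMatrix(values=empty, aggregation="mean", transform=transform)
    merged = long[long["feature_id"].isin(fluor_ids)].merge(
        metadata[["sample_id", level]], on="sample_id", how="left"
    )
    group_means = (
        merged.groupby(["feature_id", level])["intensity"].mean().unstack(level).fillna(0.0)
    )
    group_means = group_means.reindex(index=fluor_ids, columns=groups).fillna(0.0)
    selected: set[str] = set()
    for group in groups:
        col = group_means[group]
        top = col[col > 0].sort_values(ascending=False, kind="mergesort").head(k)
        selected.update(top.index)
    rows = sorted(selected)
    values = _apply_transform(group_means.loc[rows], transform)
    row_order = _leaf_order(values.to_numpy(), rows)
    col_order = _leaf_order(values.to_numpy().T, list(values.columns))
    return AggMatrix(
        values=values,
        aggregation="mean",
        transform=transform,
        row_order=row_order,
        col_order=col_order,
    )
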