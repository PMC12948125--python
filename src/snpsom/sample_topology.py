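"""Sample-space diagnostics of the portrait collection.

Portraits live in meta-SNP space; correlating them pairwise gives an S x S
similarity matrix whose block structure (after sorting samples by group)
shows intra- vs inter-group genetic cohesion.  The silhouette score turns
the same matrix (via distance 1 - r) into a per-sample measure of cluster
membership strength, with the nearest foreign group identifying where
weakly assigned samples would rather sit.  A thresholded similarity graph
with a seeded force-directed layout gives the network view.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotype_io import SampleGroups
from .som import SOMModel

__all__ = [
    "PairwiseCorrelationMap",
    "SilhouetteReport",
    "pairwise_correlation_map",
    "silhouette",
    "similarity_network",
]


@dataclass
class PairwiseCorrelationMap:
    """S x S symmetric portrait-correlation matrix, group-block ordered."""

    values: np.ndarray
    sample_ids: list[str]
    groups: SampleGroups

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape must be S x S")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")

    def group_of(self, sample_id: str) -> str:
        return self.groups.assignment[sample_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class SilhouetteReport:
    """Per-sample silhouette on distance 1 - r plus nearest foreign group."""

    table: pd.DataFrame  # columns: sample, group, silhouette, nearest_group

    @property
    def group_means(self) -> pd.Series:
        return self.table.groupby("group", sort=False)["silhouette"].mean()

    @property
    def mean(self) -> float:
        return float(self.table["silhouette"].mean())


def pairwise_correlation_map(
    model: SOMModel, groups: SampleGroups, method: str = "pearson"
) -> PairwiseCorrelationMap:
    """Pearson (or rank) correlation between every pair of sample portraits.

    Rows/columns are ordered by group blocks (group first-appearance
    order), preserving input order within each group.
    """
    if model.n_samples < 2:
        raise ValueError("need at least 2 samples")
    order = [
        sid for lab in groups.labels for sid in groups.members(lab)
        if sid in model.sample_ids
    ]
    cols = [model.sample_ids.index(sid) for sid in order]
    mat = model.codebook[:, cols].astype(float)  # M x S'
    if method == "spearman":
        from scipy.stats import rankdata

        mat = np.apply_along_axis(rankdata, 0, mat)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    sub = SampleGroups(
        assignment=groups.assignment.loc[order], palette=dict(groups.palette)
    )
    return PairwiseCorrelationMap(values=corr, sample_ids=order, groups=sub)


def silhouette(pcm: PairwiseCorrelationMap, groups: SampleGroups | None = None) -> SilhouetteReport:
    """Classic silhouette on distance d = 1 - correlation.

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean intra-group
    distance (self excluded) and b_i the smallest mean distance to any
    foreign group, which also names the nearest foreign group.  Samples in
    singleton groups get silhouette 0.
    """
    groups = groups or pcm.groups
    labels = np.asarray([groups.assignment[s] for s in pcm.sample_ids])
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 groups")
    d = 1.0 - pcm.values
    n = len(labels)
    sil = np.zeros(n)
    nearest = np.empty(n, dtype=object)
    for i in range(n):
        own = labels[i]
        own_mask = labels == own
        foreign_means = {
            lab: d[i, labels == lab].mean() for lab in uniq if lab != own
        }
        nearest[i] = min(foreign_means, key=lambda k: (foreign_means[k], uniq.index(k)))
        if own_mask.sum() == 1:
            sil[i] = 0.0
            continue
        a = d[i, own_mask].sum() / (own_mask.sum() - 1)  # exclude self (d=0)
        b = foreign_means[nearest[i]]
        sil[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    table = pd.DataFrame(
        {
            "sample": pcm.sample_ids,
            "group": labels,
            "silhouette": sil,
            "nearest_group": nearest,
        }
    )
    # within-group presentation order: descending silhouette
    table = (
        table.sort_values(["group", "silhouette"], ascending=[True, False], kind="stable")
        .reset_index(drop=True)
    )
    return SilhouetteReport(table=table)


def similarity_network(
    pcm: PairwiseCorrelationMap,
    groups: SampleGroups | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[dict[str, tuple[float, float]], pd.DataFrame]:
    """Thresholded similarity graph with a deterministic spring layout.

    Edges join sample pairs with correlation >= threshold; coordinates come
    from networkx's force-directed layout seeded for reproducibility.
    Returns (node -> (x, y), edge list frame).
    """
    graph = nx.Graph()
    graph.add_nodes_from(pcm.sample_ids)
    n = len(pcm.sample_ids)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            r = pcm.values[i, j]
            if r >= threshold:
                a, b = pcm.sample_ids[i], pcm.sample_ids[j]
                graph.add_edge(a, b, weight=float(r))
                edges.append((a, b, float(r)))
    pos = nx.spring_layout(graph, seed=seed)
    coords = {node: (float(x), float(y)) for node, (x, y) in pos.items()}
    return coords, pd.DataFrame(edges, columns=["sample_a", "sample_b", "correlation"])
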