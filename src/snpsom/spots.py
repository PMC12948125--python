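"""Spot modules: connected regions of high SNP-score on the map.

A "spot" is a module of co-mutated SNPs that shows up as a connected patch
of high meta-SNP values in a portrait.  Detection marks units at or above
a high quantile of the portrait's own values (default 0.98) and keeps
8-connected components with at least ``min_units`` units, labelling them
A, B, C... by decreasing peak value.  Summary maps aggregate detections
over many portraits; spot profiles, correlation networks and
co-occurrence networks describe how the modules behave across samples and
groups.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage

from .som import Portrait, SOMModel

__all__ = [
    "Spot",
    "SpotSet",
    "SpotNetwork",
    "detect_spots",
    "summary_maps",
    "spot_profiles",
    "spot_correlation_network",
    "spot_cooccurrence",
]

_EIGHT = np.ones((3, 3), dtype=int)


def _letter(i: int) -> str:
    letters = string.ascii_uppercase
    label = letters[i % 26]
    if i >= 26:
        label += str(i // 26)
    return label


@dataclass
class Spot:
    label: str
    units: np.ndarray  # member unit indices
    peak_value: float
    centroid: tuple[float, float]  # (row, col)
    snp_ids: list[str] = field(default_factory=list)


@dataclass
class SpotSet:
    spots: list[Spot]
    source: str
    threshold: float
    width: int
    height: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for sp in self.spots:
            u = set(int(i) for i in sp.units)
            if u & seen:
                raise ValueError("spot unit sets must be disjoint")
            seen |= u

    @property
    def labels(self) -> list[str]:
        return [sp.label for sp in self.spots]

    def unit_mask(self) -> np.ndarray:
        mask = np.zeros(self.width * self.height, dtype=bool)
        for sp in self.spots:
            mask[sp.units] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [sp.label for sp in self.spots],
                "n_units": [len(sp.units) for sp in self.spots],
                "n_snps": [len(sp.snp_ids) for sp in self.spots],
                "centroid_row": [sp.centroid[0] for sp in self.spots],
                "centroid_col": [sp.centroid[1] for sp in self.spots],
                "peak_value": [sp.peak_value for sp in self.spots],
            }
        )


@dataclass
class SpotNetwork:
    """Edges between spot labels, weighted by correlation or co-occurrence."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (a, b, weight); sign carried by weight

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if not -1.0 - 1e-12 <= w <= 1.0 + 1e-12:
                raise ValueError(f"edge weight {w} outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["spot_a", "spot_b", "weight"])


def detect_spots(
    portrait: Portrait,
    quantile: float = 0.98,
    min_units: int = 3,
    model: SOMModel | None = None,
) -> SpotSet:
    """Threshold + 8-connected-component spot detection on one portrait.

    Units with value >= the portrait's own ``quantile`` are marked; marked
    components of at least ``min_units`` units become spots, labelled by
    decreasing peak value.  A zero-range (flat) portrait has no exceedance
    structure and yields no spots.  If ``model`` is given, member SNPs are
    attached from its SNP->unit assignment.
    """
    v = portrait.grid
    if not np.isfinite(v).all():
        raise ValueError("portrait values must be finite")
    if np.ptp(v) == 0:
        return SpotSet(
            spots=[],
            source=portrait.subject,
            threshold=float("nan"),
            width=portrait.width,
            height=portrait.height,
        )
    thr = float(np.quantile(v, quantile))
    marked = v >= thr
    labels, n = ndimage.label(marked, structure=_EIGHT)
    spots: list[Spot] = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < min_units:
            continue
        rows, cols = np.nonzero(mask)
        units = (rows * portrait.width + cols).astype(int)
        spots.append(
            Spot(
                label="",
                units=np.sort(units),
                peak_value=float(v[mask].max()),
                centroid=(float(rows.mean()), float(cols.mean())),
            )
        )
    spots.sort(key=lambda sp: (-sp.peak_value, sp.units[0]))
    for i, sp in enumerate(spots):
        sp.label = _letter(i)
        if model is not None:
            sp.snp_ids = [
                model.snp_ids[j]
                for j in np.where(np.isin(model.assignment, sp.units))[0]
            ]
    return SpotSet(
        spots=spots,
        source=portrait.subject,
        threshold=thr,
        width=portrait.width,
        height=portrait.height,
    )


def summary_maps(
    portraits: list[Portrait],
    quantile: float = 0.98,
    min_units: int = 3,
    summary_quantile: float | None = None,
    model: SOMModel | None = None,
) -> tuple[np.ndarray, SpotSet]:
    """Overexpression map and its segmentation over a portrait collection.

    overexpression_map[m] is the fraction of portraits in which unit m lies
    inside a detected spot; the segmentation applies the same spot rule to
    that map (with its own quantile, default the detection quantile).
    """
    if not portraits:
        raise ValueError("empty portrait list")
    w, h = portraits[0].width, portraits[0].height
    acc = np.zeros(w * h)
    for p in portraits:
        acc += detect_spots(p, quantile=quantile, min_units=min_units).unit_mask()
    over = acc / len(portraits)
    seg_portrait = Portrait(values=over, width=w, height=h, subject="overexpression")
    seg = detect_spots(
        seg_portrait,
        quantile=summary_quantile if summary_quantile is not None else quantile,
        min_units=min_units,
        model=model,
    )
    return over, seg


def spot_profiles(spots: SpotSet, model: SOMModel) -> pd.DataFrame:
    """Per-spot, per-sample mean meta-SNP value (rows: spots, cols: samples)."""
    if spots.width != model.width or spots.height != model.height:
        raise ValueError("spot set and model grids differ")
    rows = {}
    for sp in spots.spots:
        if len(sp.units) == 0:
            raise ValueError(f"spot {sp.label} has no units")
        rows[sp.label] = model.codebook[sp.units].mean(axis=0)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=model.sample_ids
    )


def spot_correlation_network(
    profiles: pd.DataFrame, edge_threshold: float = 0.5
) -> SpotNetwork:
    """Signed Pearson-correlation edges between spot profiles.

    An edge joins each spot pair whose profile correlation magnitude
    reaches ``edge_threshold``; its weight keeps the sign (positive edges
    typically join neighboring spots, negative ones opposite map regions).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 spots")
    labels = list(profiles.index)
    vals = profiles.to_numpy(dtype=float)
    edges = []
    for i, j in combinations(range(len(labels)), 2):
        vi, vj = vals[i], vals[j]
        if vi.std() == 0 or vj.std() == 0:
            continue
        r = float(np.corrcoef(vi, vj)[0, 1])
        if abs(r) >= edge_threshold:
            edges.append((labels[i], labels[j], r))
    return SpotNetwork(nodes=labels, edges=edges)


def spot_cooccurrence(
    portraits: list[Portrait],
    reference: SpotSet,
    fraction: float = 0.5,
    quantile: float = 0.98,
    min_units: int = 3,
    presence_fraction: float = 0.5,
) -> SpotNetwork:
    """Co-occurrence edges between reference spots over a group's portraits.

    The reference segmentation serves as the shared spot atlas.  A
    reference spot is "present" in a portrait when at least
    ``presence_fraction`` of its units are marked by that portrait's own
    spot detection; spot pairs jointly present in more than ``fraction``
    of the portraits are connected, weighted by the joint fraction.
    """
    if not portraits:
        raise ValueError("empty portrait group")
    labels = reference.labels
    present = np.zeros((len(portraits), len(labels)), dtype=bool)
    for pi, p in enumerate(portraits):
        mask = detect_spots(p, quantile=quantile, min_units=min_units).unit_mask()
        for si, sp in enumerate(reference.spots):
            if len(sp.units) and mask[sp.units].mean() >= presence_fraction:
                present[pi, si] = True
    edges = []
    for i, j in combinations(range(len(labels)), 2):
        joint = float((present[:, i] & present[:, j]).mean())
        if joint > fraction:
            edges.append((labels[i], labels[j], joint))
    return SpotNetwork(nodes=labels, edges=edges)
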