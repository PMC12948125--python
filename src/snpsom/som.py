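"""Self-organizing map of SNP score profiles ("portrayal" engine).

Each SNP is one point in S-dimensional sample space (its centered
minor-allele dosage profile).  A rectangular W x H Kohonen map is trained
on these points; each unit's codebook row is a *meta-SNP* — the learned
profile of a micro-cluster of co-mutated SNPs.  Reading the codebook
column of one sample and arranging it on the grid gives that sample's
*portrait*: a topology-preserving image of its SNP landscape in which
similar co-mutation modules occupy nearby map regions.

Training is the classic online Kohonen rule with a Gaussian neighborhood:
learning rate and radius decay linearly over the total number of
presentations; the presentation order is a seeded shuffle per epoch, so
training is fully deterministic given (data, parameters, seed).
Initialization spans the grid along the first two principal directions of
the score matrix (deterministic), with a seeded random fallback.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .snp_score import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SOMModel",
    "Portrait",
    "train_som",
    "sample_portrait",
    "mean_portrait",
    "supporting_maps",
    "quantization_error",
    "save_model",
    "load_model",
]

DEFAULT_WIDTH = 45
DEFAULT_HEIGHT = 45
DEFAULT_EPOCHS = 20


@dataclass
class SOMModel:
    """Trained map: codebook of M = W*H meta-SNP profiles of length S."""

    width: int
    height: int
    codebook: np.ndarray  # M x S, unit m = (row m // W, col m % W), (0,0) top-left
    assignment: np.ndarray  # per-SNP best-matching unit index, length G
    snp_ids: list[str]
    sample_ids: list[str]
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.width * self.height
        if self.codebook.shape != (m, len(self.sample_ids)):
            raise ValueError("codebook must be (W*H) x S")
        if len(self.assignment) != len(self.snp_ids):
            raise ValueError("assignment length must equal number of SNPs")
        if not np.isfinite(self.codebook).all():
            raise ValueError("codebook contains non-finite entries")

    @property
    def n_units(self) -> int:
        return self.width * self.height

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def unit_coords(self) -> np.ndarray:
        """(M, 2) array of (row, col) per unit, row-major from top-left."""
        rows, cols = np.divmod(np.arange(self.n_units), self.width)
        return np.column_stack([rows, cols])

    def snps_in_unit(self, unit: int) -> list[str]:
        return [self.snp_ids[i] for i in np.where(self.assignment == unit)[0]]


@dataclass
class Portrait:
    """One subject's meta-SNP values laid out on the map grid."""

    values: np.ndarray  # length M, row-major, unit (0,0) top-left
    width: int
    height: int
    subject: str
    mode: str = "standard"  # standard | waterline | correlation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.width * self.height:
            raise ValueError("portrait value count must equal W*H")

    @property
    def grid(self) -> np.ndarray:
        return self.values.reshape(self.height, self.width)


def _pca_init(
    x: np.ndarray, width: int, height: int, rng: np.random.Generator
) -> np.ndarray:
    """Span the grid linearly along the first two principal directions."""
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the G x S cloud; directions live in sample space
    try:
        _, svals, vt = np.linalg.svd(xc, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - svd rarely fails
        return rng.normal(scale=0.1, size=(width * height, x.shape[1]))
    g = x.shape[0]
    scales = svals / np.sqrt(max(g, 1))
    dirs = vt[:2]
    # sign convention: largest-|.| coefficient positive, for determinism
    for i in range(dirs.shape[0]):
        j = int(np.argmax(np.abs(dirs[i])))
        if dirs[i, j] < 0:
            dirs[i] = -dirs[i]
    ax_c = np.linspace(-1.0, 1.0, width) if width > 1 else np.zeros(1)
    ax_r = np.linspace(-1.0, 1.0, height) if height > 1 else np.zeros(1)
    code = np.tile(mean, (width * height, 1))
    cc, rr = np.meshgrid(ax_c, ax_r)  # rr varies over rows
    if len(scales) >= 1 and len(dirs) >= 1:
        code += (cc.ravel()[:, None]) * scales[0] * dirs[0]
    if len(scales) >= 2 and len(dirs) >= 2:
        code += (rr.ravel()[:, None]) * scales[1] * dirs[1]
    return code


def train_som(
    scores: ScoreMatrix,
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
    sigma_start: float | None = None,
    sigma_end: float = 1.0,
    init: str = "pca",
) -> SOMModel:
    """Train the map on SNP score rows.

    Parameters follow standard Kohonen practice: the learning rate decays
    linearly from ``lr_start`` to ``lr_end`` and the Gaussian neighborhood
    radius from ``sigma_start`` (default max(W, H)/2) to ``sigma_end`` over
    ``epochs`` full presentations of the data in seeded shuffled order.
    The final SNP->unit assignment is recomputed by exhaustive best-matching
    unit search, ties broken by lowest unit index.
    """
    x = np.asarray(scores.values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("score matrix contains non-finite values")
    g, s = x.shape
    m = width * height
    if g < m:
        warnings.warn(
            f"{g} SNPs for {m} units: the map is under-populated", stacklevel=2
        )
    if np.ptp(x) == 0:
        warnings.warn("constant score matrix: codebook degenerates to a constant")
    if sigma_start is None:
        sigma_start = max(width, height) / 2.0

    rng = np.random.default_rng(seed)
    if init == "pca":
        code = _pca_init(x, width, height, rng)
    elif init == "random":
        code = rng.normal(scale=0.1, size=(m, s))
    else:
        raise ValueError(f"unknown init {init!r}")

    coords = np.column_stack(np.divmod(np.arange(m), width)).astype(float)
    total = max(epochs * g, 1)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(g)
        for i in order:
            frac = step / total
            lr = lr_start + (lr_end - lr_start) * frac
            sigma = sigma_start + (sigma_end - sigma_start) * frac
            xi = x[i]
            diff = code - xi
            bmu = int(np.argmin(np.einsum("ms,ms->m", diff, diff)))
            d2 = np.sum((coords - coords[bmu]) ** 2, axis=1)
            h = np.exp(-d2 / (2.0 * sigma * sigma))
            code -= (lr * h)[:, None] * diff
            step += 1

    assignment = _assign(x, code)
    model = SOMModel(
        width=width,
        height=height,
        codebook=code,
        assignment=assignment,
        snp_ids=list(scores.snp_ids),
        sample_ids=list(scores.sample_ids),
        training_log={
            "epochs": epochs,
            "seed": seed,
            "lr": [lr_start, lr_end],
            "sigma": [sigma_start, sigma_end],
            "init": init,
            "n_snps": g,
        },
    )
    return model


def _assign(x: np.ndarray, code: np.ndarray) -> np.ndarray:
    """Exhaustive BMU search; np.argmin breaks ties by lowest unit index."""
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2; the x term is constant per SNP
    cross = x @ code.T
    c2 = np.einsum("ms,ms->m", code, code)
    return np.argmin(c2[None, :] - 2.0 * cross, axis=1)


def quantization_error(model: SOMModel, scores: ScoreMatrix) -> float:
    """Mean Euclidean distance of each SNP row to its BMU codebook row."""
    x = np.asarray(scores.values, dtype=float)
    bmu = _assign(x, model.codebook)
    return float(np.linalg.norm(x - model.codebook[bmu], axis=1).mean())


def sample_portrait(model: SOMModel, sample_id: str) -> Portrait:
    """The portrait of one sample: codebook column arranged on the grid."""
    try:
        j = model.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample id {sample_id!r}") from None
    return Portrait(
        values=model.codebook[:, j].copy(),
        width=model.width,
        height=model.height,
        subject=sample_id,
    )


def mean_portrait(model: SOMModel, sample_set, subject: str | None = None) -> Portrait:
    """Unit-wise mean of the member portraits of ``sample_set``."""
    ids = list(sample_set)
    if not ids:
        raise ValueError("empty sample set")
    cols = []
    for sid in ids:
        try:
            cols.append(model.sample_ids.index(sid))
        except ValueError:
            raise KeyError(f"unknown sample id {sid!r}") from None
    return Portrait(
        values=model.codebook[:, cols].mean(axis=1),
        width=model.width,
        height=model.height,
        subject=subject or f"mean({len(ids)})",
    )


def supporting_maps(model: SOMModel) -> dict[str, np.ndarray]:
    """Variance map, D-map and population map, each of length M.

    variance_map[m]: variance of codebook row m across samples.
    d_map[m]: mean Euclidean distance between codebook row m and its
    8-neighborhood (edge units average over their existing neighbors).
    population_map[m]: number of SNPs assigned to unit m.
    """
    code = model.codebook
    w, h, m = model.width, model.height, model.n_units
    variance_map = code.var(axis=1)

    d_map = np.zeros(m)
    grid_idx = np.arange(m).reshape(h, w)
    for r in range(h):
        for c in range(w):
            u = grid_idx[r, c]
            dists = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        dists.append(
                            np.linalg.norm(code[u] - code[grid_idx[rr, cc]])
                        )
            d_map[u] = float(np.mean(dists)) if dists else 0.0

    population_map = np.bincount(model.assignment, minlength=m).astype(float)
    return {
        "variance_map": variance_map,
        "d_map": d_map,
        "population_map": population_map,
    }


# ---------------------------------------------------------------------------
# Persistence (directory of plain-text artifacts)
# ---------------------------------------------------------------------------

def save_model(model: SOMModel, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(model.codebook, columns=model.sample_ids).to_csv(
        d / "codebook.tsv", sep="\t", index=False, float_format="%.10g"
    )
    rows, cols = np.divmod(model.assignment, model.width)
    pd.DataFrame(
        {
            "snp_id": model.snp_ids,
            "unit_index": model.assignment,
            "row": rows,
            "col": cols,
        }
    ).to_csv(d / "assignment.tsv", sep="\t", index=False)
    log = dict(model.training_log, width=model.width, height=model.height)
    (d / "training_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def load_model(directory) -> SOMModel:
    d = Path(directory)
    log = json.loads((d / "training_log.json").read_text())
    cb = pd.read_csv(d / "codebook.tsv", sep="\t")
    asg = pd.read_csv(d / "assignment.tsv", sep="\t", dtype={"snp_id": str})
    model = SOMModel(
        width=int(log.pop("width")),
        height=int(log.pop("height")),
        codebook=cb.to_numpy(dtype=float),
        assignment=asg["unit_index"].to_numpy(dtype=int),
        snp_ids=asg["snp_id"].astype(str).tolist(),
        sample_ids=[str(c) for c in cb.columns],
        training_log=log,
    )
    return model
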