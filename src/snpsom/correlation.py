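"""Linking admixture components to map regions via rank correlation.

For each of the K ancestry components, the Q-value profile across samples
is correlated (Spearman) with every meta-SNP profile of the trained map,
giving a K x M set of correlation maps.  Meta-SNPs whose coefficient
reaches the selection threshold (default 0.7, inclusive) mark the map
region "belonging" to that component; the SNPs assigned to those units are
the component's SNP list, ready for annotation or enrichment downstream.

Selection is by correlation magnitude, not p-value, so no multiple-testing
correction is applied; the threshold trades region separation against list
size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genotype_io import QMatrix
from .som import SOMModel

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMapSet", "spearman", "correlation_maps", "map_snps_to_genes"]


@dataclass
class CorrelationMapSet:
    """Per-component Spearman maps plus thresholded meta-SNP/SNP selections."""

    maps: np.ndarray  # K x M coefficients
    component_ids: list[str]
    threshold: float
    selected_units: dict[str, np.ndarray]  # component -> unit indices
    selected_snps: dict[str, list[str]]  # component -> SNP ids
    width: int
    height: int

    def map_for(self, component: str) -> np.ndarray:
        return self.maps[self.component_ids.index(component)]

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.divmod(np.arange(self.maps.shape[1]), self.width)
        frames = []
        for i, comp in enumerate(self.component_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "component": comp,
                        "unit": np.arange(self.maps.shape[1]),
                        "row": rows,
                        "col": cols,
                        "scc": self.maps[i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _midranks(v: np.ndarray) -> np.ndarray:
    return rankdata(v, method="average")


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-ranks for ties.

    Defined as the Pearson correlation of the two mid-rank vectors.  A
    constant vector has no rank ordering; the coefficient is defined as 0
    in that case (logged) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        logger.warning("constant vector in spearman; coefficient defined as 0")
        return 0.0
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def correlation_maps(
    model: SOMModel, q: QMatrix, threshold: float = 0.7
) -> CorrelationMapSet:
    """K x M Spearman maps between Q columns and codebook rows.

    Selected meta-SNPs are exactly those with coefficient >= threshold;
    selected SNPs are the union of SNPs assigned to selected units.
    Sample registries must match by id, in order.
    """
    if list(model.sample_ids) != list(q.sample_ids):
        raise ValueError("sample order of the map and the Q matrix differ")
    code = model.codebook  # M x S
    m, s = code.shape

    # rank-transform once; constant rows handled via zero-variance guard
    rq = np.apply_along_axis(_midranks, 0, q.values)  # S x K
    rc = np.apply_along_axis(_midranks, 1, code)  # M x S
    rq_c = rq - rq.mean(axis=0, keepdims=True)
    rc_c = rc - rc.mean(axis=1, keepdims=True)
    sq = rq_c.std(axis=0)
    sc = rc_c.std(axis=1)
    n_const = int((sc == 0).sum())
    if n_const or (sq == 0).any():
        logger.warning(
            "%d constant codebook rows / %d constant Q columns: SCC set to 0",
            n_const,
            int((sq == 0).sum()),
        )
    denom = np.outer(sq, sc)  # K x M
    with np.errstate(invalid="ignore", divide="ignore"):
        maps = (rq_c.T @ rc_c.T) / s / np.where(denom == 0, np.inf, denom)

    selected_units: dict[str, np.ndarray] = {}
    selected_snps: dict[str, list[str]] = {}
    snp_ids = np.asarray(model.snp_ids, dtype=object)
    for i, comp in enumerate(q.component_ids):
        units = np.where(maps[i] >= threshold)[0]
        selected_units[comp] = units
        member = np.isin(model.assignment, units)
        selected_snps[comp] = list(snp_ids[member])
    return CorrelationMapSet(
        maps=maps,
        component_ids=list(q.component_ids),
        threshold=threshold,
        selected_units=selected_units,
        selected_snps=selected_snps,
        width=model.width,
        height=model.height,
    )


def map_snps_to_genes(snp_ids, annotation: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Join a SNP list against a user (snp_id, gene_id) table.

    Returns a per-gene count frame (duplicated (snp, gene) rows counted
    once) and the fraction of input SNPs absent from the table.
    """
    snp_ids = list(snp_ids)
    if not {"snp_id", "gene_id"} <= set(annotation.columns):
        raise ValueError("annotation table needs columns snp_id and gene_id")
    if not snp_ids:
        return pd.DataFrame(columns=["gene_id", "n_snps"]), 0.0
    ann = annotation[["snp_id", "gene_id"]].drop_duplicates()
    sel = ann[ann["snp_id"].isin(snp_ids)]
    genes = (
        sel.groupby("gene_id", sort=True)["snp_id"]
        .nunique()
        .reset_index(name="n_snps")
    )
    annotated = set(sel["snp_id"])
    frac_un = sum(1 for s in snp_ids if s not in annotated) / len(snp_ids)
    return genes, float(frac_un)
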