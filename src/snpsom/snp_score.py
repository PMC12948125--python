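"""Excess minor-allele-frequency (eMAF) SNP scores.

The SNP-score of sample s at SNP g is the minor-allele dosage x_gs in
{0,1,2} minus the mean dosage of SNP g over all samples.  Positive scores
mean the sample carries more minor alleles at that SNP than the dataset
average; the score of a SNP sums to zero over samples by construction.
Missing calls are mean-imputed before centering, so they contribute an
exact 0 — missingness is neutral for downstream map training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleGroups

logger = logging.getLogger(__name__)

__all__ = ["ScoreMatrix", "compute_snp_score", "score_density", "write_score_tsv"]


@dataclass
class ScoreMatrix:
    """G x S real matrix of centered minor-allele dosages.

    Every row has mean 0 across samples and entries in [-2, 2].
    """

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match registries")

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def compute_snp_score(g: GenotypeMatrix) -> ScoreMatrix:
    """Center each SNP's minor-allele dosage to mean zero across samples.

    Missing entries are replaced by the SNP's mean dosage over non-missing
    samples first, so after centering they are exactly 0.

    Raises
    ------
    ValueError
        If any SNP has no non-missing calls.
    """
    vals = g.values.astype(float)
    miss = g.missing_mask()
    n_called = (~miss).sum(axis=1)
    if (n_called == 0).any():
        snp = g.snp_ids[int(np.argmax(n_called == 0))]
        raise ValueError(f"SNP {snp!r} has all entries missing")
    row_mean = np.where(miss, 0.0, vals).sum(axis=1) / n_called
    vals[miss] = np.broadcast_to(row_mean[:, None], vals.shape)[miss]
    scores = vals - vals.mean(axis=1, keepdims=True)
    scores[miss] = 0.0  # exact: imputed cells sit at the row mean
    return ScoreMatrix(values=scores, snp_ids=g.snp_ids, sample_ids=g.sample_ids)


def score_density(
    scores: ScoreMatrix,
    groups: SampleGroups | None = None,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Per-group histogram of SNP-scores over [-2, 2].

    Scores of minor-allele dosages are trimodal in structured data: peaks
    near -1, 0 and +1 correspond to major-homozygous, heterozygous and
    minor-homozygous states of polymorphic SNPs (shifted by each SNP's mean).

    Returns a tidy frame with columns group, bin_left, bin_right, density.
    """
    edges = np.arange(-2.0, 2.0 + bin_width / 2, bin_width)
    if edges[-1] < 2.0:
        edges = np.append(edges, 2.0)
    out = []
    if groups is None:
        members = {"all": list(range(scores.n_samples))}
    else:
        idx = {sid: j for j, sid in enumerate(scores.sample_ids)}
        members = {
            lab: [idx[s] for s in groups.members(lab) if s in idx]
            for lab in groups.labels
        }
    for lab, cols in members.items():
        if not cols:
            logger.warning("group %r has no samples; empty density summary", lab)
            continue
        dens, _ = np.histogram(
            scores.values[:, cols].ravel(), bins=edges, density=True
        )
        out.append(
            pd.DataFrame(
                {
                    "group": lab,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "density": dens,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["group", "bin_left", "bin_right", "density"])
    return pd.concat(out, ignore_index=True)


def write_score_tsv(scores: ScoreMatrix, path) -> None:
    """Serialize scores in the genotype-TSV layout (SNP rows, sample cols)."""
    df = pd.DataFrame(scores.values, index=scores.snp_ids, columns=scores.sample_ids)
    df.to_csv(path, sep="\t", index_label="snp_id", float_format="%.10g")
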