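"""Genotype matrix I/O and allele-orientation conventions.

Genotypes are held as additive dosages in {0, 1, 2} of a *counted* allele,
with ``MISSING`` (-1) as the sentinel for no-calls.  The analysis convention
throughout the package is minor-allele counting: after
:func:`polarize_to_minor`, the allele counted by "2" is the dataset-wide
minor allele of every SNP, so 0/1/2 read as homozygous major, heterozygous
and homozygous minor.

Supported formats: PLINK 1 binary trios (.bed/.bim/.fam, SNP-major),
plain genotype TSV (SNP rows x sample columns), admixture-style .Q/.P
whitespace text, a sample-metadata TSV, and (optionally, via cyvcf2)
biallelic VCF records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SampleGroups",
    "QMatrix",
    "GenotypeFormatError",
    "read_plink",
    "write_plink",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_vcf",
    "polarize_to_minor",
    "read_q_matrix",
    "write_q_matrix",
    "read_sample_metadata",
]


class GenotypeFormatError(ValueError):
    """Raised when an on-disk genotype file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """A G x S dosage matrix plus SNP and sample registries.

    Attributes
    ----------
    values : ndarray of int8, shape (G, S)
        Dosage of the counted allele per SNP (rows) and sample (columns);
        ``MISSING`` marks no-calls.
    snps : DataFrame with columns id, chrom, pos, allele_a, allele_b
        ``allele_a`` is the counted allele (dosage 2 = two copies of it).
    samples : DataFrame with at least column id; optional group/trait columns.
    flipped : ndarray of bool, shape (G,) or None
        Per-SNP flag set by :func:`polarize_to_minor` when the orientation
        was reversed.
    """

    values: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame
    flipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D G x S array")
        g, s = self.values.shape
        if len(self.snps) != g:
            raise ValueError(f"snps registry has {len(self.snps)} rows, values has {g}")
        if len(self.samples) != s:
            raise ValueError(
                f"samples registry has {len(self.samples)} rows, values has {s}"
            )
        ok = (self.values == MISSING) | ((self.values >= 0) & (self.values <= 2))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype entry at (snp {bad[0]}, sample {bad[1]}) is "
                f"{self.values[bad[0], bad[1]]}, not in {{0,1,2,missing}}"
            )
        for name, reg in (("snp", self.snps), ("sample", self.samples)):
            dup = reg["id"][reg["id"].duplicated()]
            if len(dup):
                raise ValueError(f"duplicate {name} id {dup.iloc[0]!r}")

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["id"].tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["id"].tolist()

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING


@dataclass
class SampleGroups:
    """Per-sample categorical labels (geographic region, dominant component...)."""

    assignment: pd.Series  # index: sample id, value: label
    palette: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = self.assignment.astype(str)
        if (lab.str.len() == 0).any():
            raise ValueError("empty group label")
        self.assignment = lab

    @property
    def labels(self) -> list[str]:
        # first-appearance order, stable across calls
        return list(dict.fromkeys(self.assignment.tolist()))

    def members(self, label: str) -> list[str]:
        return self.assignment.index[self.assignment == label].tolist()

    @classmethod
    def from_q(cls, q: "QMatrix", sample_ids: list[str] | None = None) -> "SampleGroups":
        """Label each sample by its dominant admixture component."""
        ids = sample_ids if sample_ids is not None else list(q.sample_ids)
        dom = np.argmax(q.values, axis=1)
        lab = [q.component_ids[k] for k in dom]
        return cls(assignment=pd.Series(lab, index=ids))


@dataclass
class QMatrix:
    """S x K ancestry proportions; rows on the probability simplex."""

    values: np.ndarray
    component_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Q must be 2-D (S x K)")
        s, k = self.values.shape
        if len(self.component_ids) != k:
            raise ValueError("component_ids length must equal K")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(s)]
        if len(self.sample_ids) != s:
            raise ValueError("sample_ids length must equal S")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("Q entries must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("Q rows must sum to 1 within 1e-6")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> dosage of the A1 (counted) allele
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 binary trio into a :class:`GenotypeMatrix`.

    Dosages count the A1 allele of each .bim row (``allele_a``); apply
    :func:`polarize_to_minor` to enforce minor-allele counting.  SNP order
    follows the .bim file, sample order the .fam file.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(str(p))

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele_a", "allele_b"],
        dtype={"chrom": str, "id": str, "allele_a": str, "allele_b": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "id", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "id": str},
    )
    g, s = len(bim), len(fam)
    if g == 0:
        raise GenotypeFormatError(f"{bim_path}: no variants")
    if s == 0:
        raise GenotypeFormatError(f"{fam_path}: no samples")

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} (expected SNP-major PLINK bed)"
        )
    bytes_per_snp = (s + 3) // 4
    expected = 3 + bytes_per_snp * g
    if len(raw) != expected:
        raise GenotypeFormatError(
            f"{bed_path}: {len(raw)} bytes, expected {expected} for "
            f"{g} variants x {s} samples"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(g, bytes_per_snp)
    # unpack 2-bit fields, little-endian within each byte
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(g, -1)[:, :s]
    values = _BED_DECODE[codes]

    snps = bim[["id", "chrom", "pos", "allele_a", "allele_b"]].copy()
    samples = fam[["id"]].copy()
    return GenotypeMatrix(values=values, snps=snps, samples=samples)


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a PLINK 1 .bed/.bim/.fam trio (SNP-major) for ``g``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_snp, n_smp = g.values.shape
    bytes_per_snp = (n_smp + 3) // 4
    codes = np.empty((n_snp, bytes_per_snp * 4), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        lut[np.int8(dosage).view(np.uint8)] = code
    codes[:, :n_smp] = lut[g.values.view(np.uint8)]
    codes[:, n_smp:] = _BED_ENCODE[0]  # pad = hom allele_b
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": g.snps.get("chrom", pd.Series(["0"] * n_snp)),
            "id": g.snps["id"],
            "cm": 0,
            "pos": g.snps.get("pos", pd.Series(np.arange(1, n_snp + 1))),
            "allele_a": g.snps.get("allele_a", pd.Series(["A"] * n_snp)),
            "allele_b": g.snps.get("allele_b", pd.Series(["B"] * n_snp)),
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.samples["id"],
            "id": g.samples["id"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Genotype TSV
# ---------------------------------------------------------------------------

def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV: header = sample ids, first column = SNP ids,
    cells in {0, 1, 2, NA}."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise GenotypeFormatError(f"{path}: no SNP rows")
    snp_ids = df.index.astype(str)
    dup = snp_ids[snp_ids.duplicated()]
    if len(dup):
        raise GenotypeFormatError(f"{path}: duplicated SNP id {dup[0]!r}")
    values = np.full(df.shape, MISSING, dtype=np.int8)
    arr = df.to_numpy()
    for (i, j), cell in np.ndenumerate(arr):
        cell = str(cell).strip()
        if cell in ("NA", "nan", ""):
            continue
        if cell not in ("0", "1", "2"):
            raise GenotypeFormatError(
                f"{path}: invalid genotype {cell!r} at row {snp_ids[i]!r} "
                f"(line {i + 2}), column {df.columns[j]!r}"
            )
        values[i, j] = int(cell)
    snps = pd.DataFrame(
        {
            "id": snp_ids,
            "chrom": "0",
            "pos": np.arange(1, df.shape[0] + 1),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame({"id": df.columns.astype(str)})
    return GenotypeMatrix(values=values, snps=snps, samples=samples)


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        g.values.astype(object), index=g.snp_ids, columns=g.sample_ids
    )
    df[g.values == MISSING] = "NA"
    df.to_csv(path, sep="\t", index_label="snp_id")


# ---------------------------------------------------------------------------
# VCF (optional convenience; biallelic records only)
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic VCF records as ALT-allele dosages (requires cyvcf2).

    Multi-allelic records are skipped with a warning; half-missing genotypes
    become missing.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, recs = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gts = np.asarray(var.genotype.array())[:, :2]
        dos = np.where((gts < 0).any(axis=1), MISSING, gts.clip(0).sum(axis=1))
        rows.append(dos.astype(np.int8))
        recs.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "allele_a": var.ALT[0],
                "allele_b": var.REF,
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} non-biallelic records")
    if not rows:
        raise GenotypeFormatError(f"{path}: no biallelic records")
    return GenotypeMatrix(
        values=np.vstack(rows),
        snps=pd.DataFrame(recs),
        samples=pd.DataFrame({"id": sample_ids}),
    )


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Orient every SNP so the allele counted by "2" is the dataset-wide minor.

    The counted-allele frequency is computed over non-missing calls; SNPs
    with frequency > 0.5 are recoded x -> 2 - x with alleles swapped.  An
    exact tie (0.5) keeps the input orientation, which makes the operation
    idempotent.
    """
    vals = g.values.astype(np.int8).copy()
    miss = vals == MISSING
    counts = np.where(miss, 0, vals).sum(axis=1)
    n_called = (~miss).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / (2.0 * n_called)
    flip = np.nan_to_num(freq, nan=0.0) > 0.5
    vals[flip] = 2 - vals[flip]
    vals[miss] = MISSING
    snps = g.snps.copy()
    a = snps.loc[flip, "allele_a"].copy()
    snps.loc[flip, "allele_a"] = snps.loc[flip, "allele_b"]
    snps.loc[flip, "allele_b"] = a
    prev = g.flipped if g.flipped is not None else np.zeros(g.n_snps, dtype=bool)
    return replace(g, values=vals, snps=snps, flipped=prev ^ flip)


# ---------------------------------------------------------------------------
# Q / P whitespace text, sample metadata
# ---------------------------------------------------------------------------

def read_q_matrix(path, sample_ids) -> QMatrix:
    """Read admixture-style whitespace .Q text (one row per sample, K cols).

    Rows must sum to 1 within 1e-3 and are renormalized exactly.
    """
    path = Path(path)
    arr = np.loadtxt(path, dtype=float, ndmin=2)
    if arr.shape[0] != len(sample_ids):
        raise GenotypeFormatError(
            f"{path}: {arr.shape[0]} rows but {len(sample_ids)} samples expected"
        )
    sums = arr.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-3)[0]
    if len(bad):
        raise GenotypeFormatError(
            f"{path}: row {bad[0] + 1} sum {sums[bad[0]]:.6g} outside [0.999, 1.001]"
        )
    arr = arr / sums[:, None]
    k = arr.shape[1]
    return QMatrix(
        values=arr,
        component_ids=[f"k{i + 1}" for i in range(k)],
        sample_ids=list(sample_ids),
    )


def write_q_matrix(q: QMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, q.values, fmt="%.6f")


def read_sample_metadata(path, key: str = "id") -> pd.DataFrame:
    """Read a sample-metadata TSV keyed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype={key: str})
    if key not in df.columns:
        raise GenotypeFormatError(f"{path}: missing key column {key!r}")
    return df.set_index(key)
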