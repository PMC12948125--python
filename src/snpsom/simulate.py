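"""Synthetic admixed genotype data with known truth.

The generator draws the statistical structure the admixture likelihood
assumes: an ancestral minor-allele frequency per SNP, Balding-Nichols
(Beta) drift of each of K component frequencies away from it at strength
F_st, Dirichlet(alpha) admixture proportions per sample, and binomial
genotype sampling from the mixed frequency.  On top of this background, a
block of *module* SNPs per component is planted with strongly
component-specific frequencies (high in its own component, near zero in
the others), creating the co-mutated SNP modules that the map's spot
machinery is meant to find.

Presets
-------
``recovery``    K=3, G=2000, S=300, F_st=0.2, alpha=0.2, 100 module SNPs
                per component — the standard parameter-recovery setting.
``laucou-like`` K=6, G=10000, S=780, ~300 module SNPs per component —
                echoes the scale of a genotyping-array study of ~10k SNPs
                by ~780 accessions.
``overlap``     as recovery but F_st=0.05 — weakly differentiated
                components for stress-testing cluster diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, QMatrix

__all__ = ["SimulationTruth", "simulate_admixed", "desk_profile"]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    q: QMatrix  # S x K true admixture proportions
    p: np.ndarray  # K x G true component frequencies
    module_of: pd.Series  # per-SNP component label or "background"
    params: dict

    def module_snps(self, component: str) -> list[str]:
        return self.module_of.index[self.module_of == component].tolist()


def simulate_admixed(
    K: int = 3,
    G: int = 2000,
    S: int = 300,
    f_st: float = 0.2,
    alpha: float = 0.2,
    n_module_snps_per_component: int = 100,
    seed: int = 0,
    module_high: tuple[float, float] = (0.6, 0.9),
    module_low: tuple[float, float] = (0.0, 0.1),
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw one admixed dataset; see module docstring for the model.

    Returns the genotype matrix (minor-allele dosages, already polarized by
    construction in expectation — callers should still run
    ``polarize_to_minor`` as with real data) and the simulation truth.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 < f_st < 1:
        raise ValueError("f_st must lie in (0, 1)")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if n_module_snps_per_component < 0 or G <= K * n_module_snps_per_component:
        raise ValueError("need G > K * n_module_snps_per_component")

    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.5, size=G)
    shape_a = p0 * (1.0 - f_st) / f_st
    shape_b = (1.0 - p0) * (1.0 - f_st) / f_st
    p = rng.beta(shape_a[None, :], shape_b[None, :], size=(K, G))

    module_of = np.array(["background"] * G, dtype=object)
    nm = n_module_snps_per_component
    for k in range(K):
        lo, hi = k * nm, (k + 1) * nm
        module_of[lo:hi] = f"k{k + 1}"
        p[:, lo:hi] = rng.uniform(module_low[0], module_low[1], size=(K, nm))
        p[k, lo:hi] = rng.uniform(module_high[0], module_high[1], size=nm)
    p = np.clip(p, 1e-6, 1 - 1e-6)

    q = rng.dirichlet(np.full(K, alpha), size=S)
    freq = q @ p  # S x G mixed minor-allele frequency
    x = rng.binomial(2, freq).astype(np.int8).T  # G x S

    snp_ids = [f"snp{i:05d}" for i in range(G)]
    sample_ids = [f"acc{j:04d}" for j in range(S)]
    geno = GenotypeMatrix(
        values=x,
        snps=pd.DataFrame(
            {
                "id": snp_ids,
                "chrom": "1",
                "pos": np.arange(1, G + 1),
                "allele_a": "A",
                "allele_b": "B",
            }
        ),
        samples=pd.DataFrame({"id": sample_ids}),
    )
    truth = SimulationTruth(
        q=QMatrix(
            values=q,
            component_ids=[f"k{i + 1}" for i in range(K)],
            sample_ids=sample_ids,
        ),
        p=p,
        module_of=pd.Series(module_of, index=snp_ids),
        params={
            "K": K,
            "G": G,
            "S": S,
            "f_st": f_st,
            "alpha": alpha,
            "n_module_snps_per_component": n_module_snps_per_component,
            "seed": seed,
        },
    )
    return geno, truth


_PRESETS = MappingProxyType(
    {
        "recovery": MappingProxyType(
            dict(K=3, G=2000, S=300, f_st=0.2, alpha=0.2,
                 n_module_snps_per_component=100)
        ),
        "laucou-like": MappingProxyType(
            dict(K=6, G=10000, S=780, f_st=0.2, alpha=0.2,
                 n_module_snps_per_component=300)
        ),
        "overlap": MappingProxyType(
            dict(K=3, G=2000, S=300, f_st=0.05, alpha=0.2,
                 n_module_snps_per_component=100)
        ),
    }
)


def desk_profile(name: str | None = None):
    """Canonical simulation parameter sets (immutable).

    With no argument, returns the read-only mapping of all presets; with a
    preset name, returns that preset's parameter dict (mutable copy).
    """
    if name is None:
        return _PRESETS
    try:
        return dict(_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
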