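"""Admixture proportion estimation under the binomial mixture likelihood.

Model: sample s draws each of its two allele copies at SNP g from ancestral
population k with probability q_sk, and that copy is the minor allele with
probability p_kg.  The dosage x_sg is then Binomial(2, f_sg) with
f_sg = sum_k q_sk p_kg, giving the log-likelihood

    L(Q, P) = sum_{s,g} [ x_sg ln f_sg + (2 - x_sg) ln(1 - f_sg) ]

(up to the binomial constant), maximized here by EM.  Each EM sweep
attributes minor/major allele copies to components in proportion to their
posterior responsibility and re-estimates Q rows (simplex) and P entries
(clamped to [eps, 1-eps]); the likelihood is non-decreasing by construction.

Cross-validation masks individual genotype *entries* (not whole samples):
each fold's entries are hidden, the model refit, and the hidden dosages
predicted as 2 f_sg; the CV error is the mean squared deviation over the
masked entries, averaged over folds.  Comparing the curve across K is the
standard device for choosing the number of ancestral components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, QMatrix

__all__ = [
    "PMatrix",
    "CVCurve",
    "fit_admixture",
    "cv_error",
    "cv_curve",
    "align_components",
    "write_p_matrix",
]

EPS = 1e-6


@dataclass
class PMatrix:
    """K x G component allele frequencies, clamped inside (0, 1)."""

    values: np.ndarray
    component_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.component_ids), len(self.snp_ids)):
            raise ValueError("P must be K x G matching the registries")
        if ((self.values < EPS - 1e-12) | (self.values > 1 - EPS + 1e-12)).any():
            raise ValueError("P entries must lie in [eps, 1-eps]")


@dataclass
class CVCurve:
    """Cross-validation error per candidate K."""

    ks: list[int]
    errors: list[float]
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.errors):
            raise ValueError("one error per requested K")
        if any(e < 0 for e in self.errors):
            raise ValueError("CV errors must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.ks, "cv_error": self.errors})


def _masked_loglik(x: np.ndarray, known: np.ndarray, f: np.ndarray) -> float:
    f = np.clip(f, EPS, 1 - EPS)
    ll = np.where(known, x * np.log(f) + (2.0 - x) * np.log1p(-f), 0.0)
    return float(ll.sum())


def fit_admixture(
    g: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-4,
    _mask_extra: np.ndarray | None = None,
) -> tuple[QMatrix, PMatrix, list[float]]:
    """Maximum-likelihood Q (S x K) and P (K x G) by EM.

    Missing genotype entries are skipped in the likelihood.  Q is
    initialized from Dirichlet(1) draws and P from seed-perturbed overall
    allele frequencies, so runs are reproducible given ``seed``.  Returns
    the fitted matrices plus the (non-decreasing) log-likelihood trace.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_samples:
        raise ValueError(f"K={K} exceeds the number of samples S={g.n_samples}")
    x = g.values.T.astype(float)  # S x G
    known = g.values.T != MISSING
    if _mask_extra is not None:
        known = known & ~_mask_extra
    if not known.any():
        raise ValueError("no non-missing genotype entries")
    x = np.where(known, x, 0.0)

    s, n_g = x.shape
    rng = np.random.default_rng(seed)

    # overall minor-allele frequency per SNP from visible entries
    n_vis = known.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        base = x.sum(axis=0) / (2.0 * np.maximum(n_vis, 1))
    base = np.clip(base, EPS, 1 - EPS)

    if K == 1:
        q = np.ones((s, 1))
        p = base[None, :].copy()
        f = np.clip(q @ p, EPS, 1 - EPS)
        trace = [_masked_loglik(x, known, f)]
        return _package(q, p, trace, g)

    q = rng.dirichlet(np.ones(K), size=s)
    p = np.clip(base[None, :] + rng.normal(scale=0.05, size=(K, n_g)), EPS, 1 - EPS)

    n_known_per_sample = known.sum(axis=1).astype(float)  # total copies / 2
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        f = np.clip(q @ p, EPS, 1 - EPS)  # S x G
        ll = _masked_loglik(x, known, f)
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll

        # responsibilities: minor copies a_sgk, major copies b_sgk
        minor_w = np.where(known, x / f, 0.0)  # S x G
        major_w = np.where(known, (2.0 - x) / (1.0 - f), 0.0)
        a_sum_g = np.empty((s, K))  # sum over g of a_sgk
        a_sum_s = np.empty((K, n_g))  # sum over s of a_sgk
        ab_sum_s = np.empty((K, n_g))
        for k in range(K):
            qp = q[:, k][:, None] * p[k][None, :]
            q1p = q[:, k][:, None] * (1.0 - p[k])[None, :]
            a = minor_w * qp
            b = major_w * q1p
            a_sum_g[:, k] = a.sum(axis=1) + b.sum(axis=1)
            a_sum_s[k] = a.sum(axis=0)
            ab_sum_s[k] = a.sum(axis=0) + b.sum(axis=0)
        q = a_sum_g / (2.0 * n_known_per_sample[:, None])
        q = q / q.sum(axis=1, keepdims=True)
        p = np.clip(a_sum_s / np.maximum(ab_sum_s, 1e-300), EPS, 1 - EPS)

    return _package(q, p, trace, g)


def _package(q, p, trace, g: GenotypeMatrix):
    k = q.shape[1]
    comp = [f"k{i + 1}" for i in range(k)]
    qm = QMatrix(
        values=np.clip(q, 0.0, 1.0) / np.clip(q, 0.0, 1.0).sum(axis=1, keepdims=True),
        component_ids=comp,
        sample_ids=g.sample_ids,
    )
    pm = PMatrix(values=p, component_ids=comp, snp_ids=g.snp_ids)
    return qm, pm, trace


def cv_error(
    g: GenotypeMatrix,
    K: int,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-3,
) -> float:
    """Entry-masking cross-validation error for one K.

    Non-missing entries are partitioned into ``n_folds`` folds by seed;
    each fold is masked, the model refit on the rest, and the masked
    dosages predicted as 2 * sum_k q_sk p_kg.  Returns the mean squared
    prediction error averaged over folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    known = (g.values != MISSING).T  # S x G
    idx = np.argwhere(known)
    if len(idx) < n_folds:
        raise ValueError("fewer non-missing entries than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(idx))
    fold_of = np.empty(len(idx), dtype=int)
    fold_of[perm] = np.arange(len(idx)) % n_folds

    x = g.values.T.astype(float)
    errors = []
    for fold in range(n_folds):
        sel = idx[fold_of == fold]
        if len(sel) == 0:
            raise ValueError(f"fold {fold} has zero entries")
        mask = np.zeros_like(known)
        mask[sel[:, 0], sel[:, 1]] = True
        qm, pm, _ = fit_admixture(
            g, K, seed=seed + 1000 + fold, max_iter=max_iter, tol=tol,
            _mask_extra=mask,
        )
        pred = 2.0 * (qm.values @ pm.values)
        resid = pred[sel[:, 0], sel[:, 1]] - x[sel[:, 0], sel[:, 1]]
        errors.append(float(np.mean(resid**2)))
    return float(np.mean(errors))


def cv_curve(
    g: GenotypeMatrix,
    ks,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-3,
) -> CVCurve:
    """CV error across a range of K (the device behind the K-selection plot)."""
    ks = list(ks)
    errs = [
        cv_error(g, k, n_folds=n_folds, seed=seed, max_iter=max_iter, tol=tol)
        for k in ks
    ]
    return CVCurve(ks=ks, errors=errs, n_folds=n_folds, seed=seed)


def align_components(q_ref: QMatrix, q_new: QMatrix) -> tuple[QMatrix, list[int]]:
    """Match q_new's components to q_ref's by greedy maximum correlation.

    EM estimates are identified only up to a permutation of component
    labels ("label switching"); alignment makes runs at the same or growing
    K comparable.  Components of q_new left unmatched (K_new > K_ref) are
    appended in their given order.  Returns the realigned QMatrix and the
    column permutation applied (new order in terms of q_new's columns).
    """
    if list(q_ref.sample_ids) != list(q_new.sample_ids):
        raise ValueError("sample registries differ between the two Q matrices")
    k_ref, k_new = q_ref.n_components, q_new.n_components
    a = q_ref.values
    b = q_new.values
    with np.errstate(invalid="ignore"):
        corr = np.zeros((k_ref, k_new))
        for i in range(k_ref):
            for j in range(k_new):
                sa, sb = a[:, i].std(), b[:, j].std()
                if sa == 0 or sb == 0:
                    corr[i, j] = 0.0
                else:
                    corr[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    order: list[int | None] = [None] * k_ref
    used: set[int] = set()
    work = corr.copy()
    for _ in range(min(k_ref, k_new)):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        order[i] = int(j)
        used.add(int(j))
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    perm = [j for j in order if j is not None]
    perm += [j for j in range(k_new) if j not in used]
    aligned = QMatrix(
        values=b[:, perm],
        component_ids=[q_new.component_ids[j] for j in perm],
        sample_ids=list(q_new.sample_ids),
    )
    return aligned, perm


def write_p_matrix(p: PMatrix, path) -> None:
    """Whitespace text, one row per SNP, K columns (external .P layout)."""
    np.savetxt(path, p.values.T, fmt="%.6f")
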