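"""Ensemble-sampling similarity: PCA + RMSIP, clustering-based ensemble
similarity (CES) and dimensionality-reduction-based ensemble similarity
(DRES).

RMSIP measures the overlap of the essential subspaces (first D principal
components, D = 10 by default) of two ensembles and ranges from 0 (no
correlation of the sampled phase space) to 1 (completely overlapping).
CES and DRES compare full probability distributions via the Jensen-Shannon
divergence (natural log, so the upper bound is ln 2 ≈ 0.693): CES clusters
the pooled frames with affinity propagation on the pairwise Cα-RMSD matrix
and compares cluster-population vectors; DRES embeds the pooled RMSD matrix
with stochastic proximity embedding, estimates per-ensemble densities by
Gaussian KDE and evaluates the divergence by Monte-Carlo sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Ensemble, ValidationError, resolve_selection

__all__ = [
    "PCABasis",
    "SimilarityMatrix",
    "pca_ensemble",
    "rmsip",
    "pairwise_rmsd_matrix",
    "jensen_shannon_divergence",
    "ces",
    "dres",
    "similarity_heatmap",
]

LN2 = float(np.log(2.0))


@dataclass
class PCABasis:
    """Mean structure plus orthonormal eigenvectors of the coordinate
    covariance, in descending eigenvalue order (nm²)."""

    mean_structure: np.ndarray
    eigenvectors: np.ndarray        # (3N, K) columns
    eigenvalues: np.ndarray         # (K,) descending

    def __post_init__(self) -> None:
        self.mean_structure = np.asarray(self.mean_structure, float)
        self.eigenvectors = np.asarray(self.eigenvectors, float)
        self.eigenvalues = np.asarray(self.eigenvalues, float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValidationError("eigenvalues must be sorted descending")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValidationError("eigenvectors are not orthonormal")

    @property
    def n_components(self) -> int:
        return int(self.eigenvalues.size)


@dataclass
class SimilarityMatrix:
    """Symmetric all-vs-all replicate comparison (RMSIP or JSD)."""

    ids: list[str]
    values: np.ndarray
    metric: str                     # rmsip | ces_jsd | dres_jsd

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape must match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("similarity matrix must be symmetric")
        diag = np.diag(self.values)
        if self.metric == "rmsip":
            if not np.allclose(diag, 1.0, atol=1e-9):
                raise ValidationError("RMSIP diagonal must be 1")
            if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
                raise ValidationError("RMSIP values must lie in [0, 1]")
        elif self.metric in ("ces_jsd", "dres_jsd"):
            if not np.allclose(diag, 0.0, atol=1e-9):
                raise ValidationError("JSD diagonal must be 0")
            if np.any(self.values < -1e-12) or np.any(self.values > LN2 + 1e-6):
                raise ValidationError("JSD values must lie in [0, ln 2]")
        else:
            raise ValidationError(f"unknown metric {self.metric!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def mean_offdiagonal(self) -> np.ndarray:
        """Per-replicate mean of off-diagonal entries (outlier flagging)."""
        n = len(self.ids)
        if n < 2:
            return np.zeros(n)
        mask = ~np.eye(n, dtype=bool)
        return np.array([self.values[i][mask[i]].mean() for i in range(n)])


# ---------------------------------------------------------------------------
# PCA and RMSIP
# ---------------------------------------------------------------------------

def pca_ensemble(ensemble: Ensemble, selection: str = "calpha") -> PCABasis:
    """Eigendecomposition of the Cα coordinate covariance (frames should be
    superposed on a common reference first).  Returns the full basis; a
    constant trajectory yields all-zero eigenvalues."""
    idx = resolve_selection(ensemble.topology, selection)
    if idx.size == 0:
        raise ValidationError(f"selection {selection!r} matches no atoms")
    if ensemble.n_frames < 2:
        raise ValidationError("PCA needs at least two frames")
    X = ensemble.frames[:, idx].reshape(ensemble.n_frames, -1)
    mean = X.mean(axis=0)
    cov = np.cov(X.T, ddof=1) if X.shape[1] > 1 else np.atleast_2d(np.var(X, ddof=1))
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    return PCABasis(mean_structure=mean, eigenvectors=vecs[:, order],
                    eigenvalues=vals)


def rmsip(basis_a: PCABasis, basis_b: PCABasis, n_components: int = 10) -> float:
    """Root mean square inner product over the first ``n_components``
    principal components: sqrt((1/D) Σ_ij (v_i·w_j)²) ∈ [0, 1]."""
    if basis_a.eigenvectors.shape[0] != basis_b.eigenvectors.shape[0]:
        raise ValidationError("PCA bases live in different dimensions")
    D = int(n_components)
    if basis_a.n_components < D or basis_b.n_components < D:
        raise ValidationError(
            f"both bases need >= {D} components "
            f"(have {basis_a.n_components} and {basis_b.n_components})"
        )
    A = basis_a.eigenvectors[:, :D]
    B = basis_b.eigenvectors[:, :D]
    return float(np.sqrt(np.sum((A.T @ B) ** 2) / D))


def rmsip_matrix(ensembles: list[Ensemble], n_components: int = 10,
                 selection: str = "calpha") -> SimilarityMatrix:
    """All-vs-all RMSIP between replicate ensembles."""
    bases = [pca_ensemble(e, selection) for e in ensembles]
    n = len(bases)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = rmsip(bases[i], bases[j], n_components)
    return SimilarityMatrix([e.replicate_id for e in ensembles], vals, "rmsip")


# ---------------------------------------------------------------------------
# Pairwise RMSD matrix (blocked batched Kabsch)
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(coords: np.ndarray, block: int = 256) -> np.ndarray:
    """All-pairs least-squares-fitted RMSD (nm) of ``coords``
    ``(n_frames, n_atoms, 3)`` via batched 3×3 SVDs."""
    coords = np.asarray(coords, float)
    n, n_atoms, _ = coords.shape
    Xc = coords - coords.mean(axis=1, keepdims=True)
    G = np.einsum("kij,kij->k", Xc, Xc)
    out = np.zeros((n, n))
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for j0 in range(i0, n, block):
            j1 = min(j0 + block, n)
            C = np.einsum("aij,bik->abjk", Xc[i0:i1], Xc[j0:j1])
            s = np.linalg.svd(C, compute_uv=False)
            sign = np.sign(np.linalg.det(C))
            sign[sign == 0] = 1.0
            tr = s[..., 0] + s[..., 1] + sign * s[..., 2]
            msd = (G[i0:i1, None] + G[None, j0:j1] - 2.0 * tr) / n_atoms
            out[i0:i1, j0:j1] = np.sqrt(np.clip(msd, 0.0, None))
    iu = np.triu_indices(n, 1)
    out[(iu[1], iu[0])] = out[iu]
    np.fill_diagonal(out, 0.0)
    return out


def _pool_frames(ensembles: list[Ensemble], selection: str,
                 max_pooled: int) -> tuple[np.ndarray, np.ndarray]:
    if len(ensembles) < 2:
        raise ValidationError("need at least two ensembles to compare")
    n_atoms = ensembles[0].n_atoms
    for e in ensembles[1:]:
        if e.n_atoms != n_atoms:
            raise ValidationError("ensembles do not share a topology")
    total = sum(e.n_frames for e in ensembles)
    stride = max(1, int(np.ceil(total / max_pooled)))
    pooled, owner = [], []
    for k, e in enumerate(ensembles):
        idx = resolve_selection(e.topology, selection)
        sel = e.frames[::stride, idx]
        pooled.append(sel)
        owner.append(np.full(sel.shape[0], k))
    return np.concatenate(pooled), np.concatenate(owner)


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence
# ---------------------------------------------------------------------------

def jensen_shannon_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Discrete JSD in nats: H((P+Q)/2) − H(P)/2 − H(Q)/2, bounded by ln 2."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValidationError("distributions must share support")

    def entropy(v):
        nz = v[v > 0]
        return float(-(nz * np.log(nz)).sum())

    m = 0.5 * (p + q)
    return max(0.0, entropy(m) - 0.5 * entropy(p) - 0.5 * entropy(q))


# ---------------------------------------------------------------------------
# CES
# ---------------------------------------------------------------------------

def ces(ensembles: list[Ensemble], preference: float = -10.0,
        selection: str = "calpha", max_pooled: int = 3000,
        damping: float = 0.9, max_iter: int = 1000,
        convergence_iter: int = 50) -> SimilarityMatrix:
    """Clustering-based ensemble similarity.

    Pools all frames, clusters the pooled pairwise Cα-RMSD matrix with
    affinity propagation (similarity = −RMSD in nm; the ``preference`` is in
    those units), converts each ensemble into a cluster-population
    probability vector, and returns the pairwise discrete JSD matrix.
    Frames are strided so at most ``max_pooled`` enter the O(n²) step.
    """
    from sklearn.cluster import AffinityPropagation
    from sklearn.exceptions import ConvergenceWarning

    pooled, owner = _pool_frames(ensembles, selection, max_pooled)
    D = pairwise_rmsd_matrix(pooled)
    ap = AffinityPropagation(
        affinity="precomputed", preference=preference, damping=damping,
        max_iter=max_iter, convergence_iter=convergence_iter, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            labels = ap.fit_predict(-D)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"affinity propagation did not converge within {max_iter} "
                f"iterations (preference={preference}, damping={damping})"
            ) from exc
    n_clusters = int(labels.max()) + 1
    n_ens = len(ensembles)
    pops = np.zeros((n_ens, n_clusters))
    for k in range(n_ens):
        counts = np.bincount(labels[owner == k], minlength=n_clusters)
        pops[k] = counts / counts.sum()
    vals = np.zeros((n_ens, n_ens))
    for i in range(n_ens):
        for j in range(i + 1, n_ens):
            vals[i, j] = vals[j, i] = jensen_shannon_divergence(pops[i], pops[j])
    mat = SimilarityMatrix([e.replicate_id for e in ensembles], vals, "ces_jsd")
    mat.cluster_populations = pops          # exposed for cross-checks
    mat.cluster_labels = labels
    return mat


# ---------------------------------------------------------------------------
# DRES
# ---------------------------------------------------------------------------

def spe_embed(distances: np.ndarray, dim: int = 6, seed: int = 0,
              n_cycles: int = 300, sweeps_per_cycle: int = 16,
              lam_initial: float = 1.0, lam_final: float = 0.01) -> np.ndarray:
    """Stochastic proximity embedding of a dissimilarity matrix.

    Random disjoint pairs are pulled toward / pushed from each other so
    embedded distances match the input; the neighbourhood radius anneals
    from the maximum dissimilarity down to its 1st percentile while the
    learning rate decays from ``lam_initial`` to ``lam_final``.  Each sweep
    pairs every point at most once, so updates never act on stale
    positions.
    """
    n = distances.shape[0]
    if n < dim + 1:
        raise ValidationError(f"need more than dim={dim} points to embed")
    rng = np.random.default_rng(seed)
    scale = float(distances.max()) or 1.0
    X = rng.uniform(0.0, scale, size=(n, dim))
    offdiag = distances[np.triu_indices(n, 1)]
    rc_final = float(np.percentile(offdiag, 1.0))
    rc_sched = np.linspace(scale, max(rc_final, 1e-6), n_cycles)
    lam_sched = np.geomspace(lam_initial, max(lam_final, 1e-6), n_cycles)
    half = n // 2
    eps = 1e-10
    for rc, lam in zip(rc_sched, lam_sched):
        for _ in range(sweeps_per_cycle):
            perm = rng.permutation(n)
            i, j = perm[:half], perm[half:2 * half]
            dt = distances[i, j]
            diff = X[i] - X[j]
            de = np.linalg.norm(diff, axis=1)
            upd = (dt <= rc) | (de < dt)
            ii, jj = i[upd], j[upd]
            step = (lam * 0.5 * (dt[upd] - de[upd])
                    / (de[upd] + eps))[:, None] * diff[upd]
            X[ii] += step
            X[jj] -= step
    return X


def dres(ensembles: list[Ensemble], dim: int = 6, seed: int = 0,
         selection: str = "calpha", max_pooled: int = 3000,
         n_mc: int = 10000, n_cycles: int = 300) -> SimilarityMatrix:
    """Dimensionality-reduction-based ensemble similarity.

    Embeds the pooled pairwise Cα-RMSD matrix into ``dim`` dimensions with
    SPE, fits a Gaussian KDE per ensemble in the embedded space (Scott's
    rule) and estimates pairwise JSD by Monte-Carlo sampling from the two
    densities; values are clipped to [0, ln 2].  Deterministic for a fixed
    seed.
    """
    from scipy.stats import gaussian_kde

    pooled, owner = _pool_frames(ensembles, selection, max_pooled)
    D = pairwise_rmsd_matrix(pooled)
    X = spe_embed(D, dim=dim, seed=seed, n_cycles=n_cycles)
    n_ens = len(ensembles)
    kdes = []
    for k in range(n_ens):
        pts = X[owner == k].T
        try:
            kdes.append(gaussian_kde(pts))
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                "KDE bandwidth degenerate (all embedded points identical); "
                "add jitter to the input ensembles"
            ) from exc
    rng = np.random.default_rng(seed + 1)
    vals = np.zeros((n_ens, n_ens))
    half = n_mc // 2
    for i in range(n_ens):
        for j in range(i + 1, n_ens):
            xs_p = kdes[i].resample(half, seed=rng.integers(0, 2**31 - 1))
            xs_q = kdes[j].resample(half, seed=rng.integers(0, 2**31 - 1))
            eps = 1e-300
            p_p, q_p = kdes[i](xs_p) + eps, kdes[j](xs_p) + eps
            p_q, q_q = kdes[i](xs_q) + eps, kdes[j](xs_q) + eps
            m_p = 0.5 * (p_p + q_p)
            m_q = 0.5 * (p_q + q_q)
            jsd = 0.5 * np.mean(np.log(p_p / m_p)) + \
                0.5 * np.mean(np.log(q_q / m_q))
            vals[i, j] = vals[j, i] = float(np.clip(jsd, 0.0, LN2))
    return SimilarityMatrix([e.replicate_id for e in ensembles], vals, "dres_jsd")


# ---------------------------------------------------------------------------
# Heatmap rendering
# ---------------------------------------------------------------------------

def similarity_heatmap(matrix: SimilarityMatrix, out_path) -> None:
    """Render a labelled heatmap (PNG) with a TSV twin alongside it.  JSD
    color scales are capped at ln 2; RMSIP at 1."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not matrix.ids:
        raise ValidationError("similarity matrix has no replicate ids")
    out_path = str(out_path)
    vmax = 1.0 if matrix.metric == "rmsip" else LN2
    fig, ax = plt.subplots(figsize=(4 + 0.3 * len(matrix.ids),
                                    3.5 + 0.3 * len(matrix.ids)))
    im = ax.imshow(matrix.values, vmin=0.0, vmax=vmax,
                   cmap="viridis" if matrix.metric == "rmsip" else "magma")
    ax.set_xticks(range(len(matrix.ids)), matrix.ids, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.ids)), matrix.ids)
    ax.set_title(matrix.metric)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    tsv = out_path.rsplit(".", 1)[0] + ".tsv"
    matrix.to_frame().to_csv(tsv, sep="\t")
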