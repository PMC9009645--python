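"""Ordination and clustering of genetic distance matrices.

Population structure in a fingerprinted collection is summarized by
classical principal coordinate analysis (PCoA, metric multidimensional
scaling) of the pairwise distance matrix, followed by partitioning around
medoids (PAM, k-medoids) on the principal coordinates.  Clustering on
coordinates rather than on the raw dissimilarities improves recovery of the
true number of groups for large binary-ish genetic data; the number of
clusters is chosen by inspecting the total within-cluster sum of squares
curve, with the mean silhouette width as the automated criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score

__all__ = ["PCoAResult", "pcoa", "ClusteringResult", "pam", "KDiagnostics", "choose_k"]

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class PCoAResult:
    """Principal coordinates: samples x axes, with eigenvalues and the
    fraction of positive-eigenvalue variance each axis explains."""

    labels: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray


def pcoa(dm: DistanceMatrix, axes: int | None = None) -> PCoAResult:
    """Classical scaling (Torgerson/Gower) of a distance matrix.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and retains the
    positive-eigenvalue axes (up to ``axes`` if given).  Negative eigenvalues
    (non-Euclidean input) are dropped without correction; explained variance
    is normalized over the positive eigenvalues only.
    """
    if axes is not None and axes < 1:
        raise ValueError("axes must be >= 1")
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0) if evals.size else 1.0
    pos = evals > _EIG_TOL * scale
    evals_pos, evecs_pos = evals[pos], evecs[:, pos]
    if axes is not None:
        evals_pos, evecs_pos = evals_pos[:axes], evecs_pos[:, :axes]
    coords = evecs_pos * np.sqrt(evals_pos)
    total_pos = evals[evals > _EIG_TOL * scale].sum()
    explained = evals_pos / total_pos if total_pos > 0 else np.zeros_like(evals_pos)
    return PCoAResult(
        labels=tuple(dm.ids),
        coordinates=coords,
        eigenvalues=evals_pos,
        explained=explained,
    )


@dataclass(frozen=True)
class ClusteringResult:
    """PAM clustering: medoid labels, per-sample cluster assignment, total
    within-cluster sum of squared distances to the medoid, and the mean
    silhouette width (NaN for k = 1 or k = n)."""

    k: int
    medoids: tuple[str, ...]
    labels: dict[str, int]
    wss: float
    silhouette: float


def _pam_core(d: np.ndarray, k: int) -> tuple[list[int], np.ndarray]:
    """BUILD + SWAP k-medoids on a precomputed distance matrix.

    Deterministic: BUILD adds the point with the largest decrease of total
    cost (ties to the lowest index); SWAP applies the best strictly-improving
    (medoid, non-medoid) exchange until none exists.
    """
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        best_j, best_gain = None, -np.inf
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(cur - d[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_j, best_gain = j, gain
        medoids.append(best_j)

    def cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (current, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = cost(trial)
                if c < best[0] - 1e-12:
                    best = (c, mi, h)
        if best[1] is not None:
            current = best[0]
            medoids[best[1]] = best[2]
            improved = True
    medoids = sorted(medoids)
    labels = np.argmin(d[:, medoids], axis=1)
    return medoids, labels


def pam(points: np.ndarray, k: int, labels: list[str] | None = None,
        seed: int = 0) -> ClusteringResult:
    """Partitioning around medoids on Euclidean distances over coordinates.

    The algorithm is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages of the pipeline.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    ids = list(labels) if labels is not None else [str(i) for i in range(n)]
    d = cdist(pts, pts)
    medoids, assign = _pam_core(d, k)
    wss = float(sum(d[i, medoids[assign[i]]] ** 2 for i in range(n)))
    if 1 < k < n and len(set(assign.tolist())) > 1:
        sil = float(silhouette_score(pts, assign))
    else:
        sil = float("nan")
    return ClusteringResult(
        k=k,
        medoids=tuple(ids[m] for m in medoids),
        labels={ids[i]: int(assign[i]) for i in range(n)},
        wss=wss,
        silhouette=sil,
    )


@dataclass(frozen=True)
class KDiagnostics:
    """k-selection diagnostics: the WSS elbow curve (for inspection) and the
    silhouette curve; ``recommended`` is the silhouette argmax."""

    ks: tuple[int, ...]
    wss: tuple[float, ...]
    silhouette: tuple[float, ...]
    recommended: int
    results: tuple[ClusteringResult, ...]


def choose_k(points: np.ndarray, k_range: range | tuple[int, int] = (2, 8),
             labels: list[str] | None = None, seed: int = 0) -> KDiagnostics:
    """Scan k over a range, returning WSS and silhouette curves.

    The recommendation is the k maximizing the mean silhouette width; the
    WSS curve is reported for visual elbow inspection.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if np.allclose(cdist(pts, pts), 0.0):
        raise ValueError("all points identical: clustering is degenerate")
    if isinstance(k_range, range):
        ks = [k for k in k_range]
    else:
        lo, hi = k_range
        ks = list(range(lo, hi + 1))
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range leaves no feasible k in [2, n-1]")
    results = [pam(pts, k, labels=labels, seed=seed) for k in ks]
    sils = [r.silhouette for r in results]
    best = int(np.nanargmax(sils))
    return KDiagnostics(
        ks=tuple(ks),
        wss=tuple(r.wss for r in results),
        silhouette=tuple(sils),
        recommended=ks[best],
        results=tuple(results),
    )
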