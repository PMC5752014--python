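"""Single-table ordinations: PCA, principal coordinates with Cailliez
correction, patristic distances, and great-circle geographic distances.

These are the three preliminary analyses of the integrative workflow: a
correlation PCA of the standardized morphometric table, a PCoA of the
patristic distance matrix (Cailliez-corrected when the tree metric is not
Euclidean), and a PCoA of the pairwise geographic distance matrix.

Conventions
-----------
Row weights are uniform 1/n throughout, so the PCA of a centred-reduced table
has total inertia equal to its column count, and PCoA eigenvalues are the
inertias of the principal coordinates under the same weighting.  Axis signs
are fixed by making the first non-negligible score/loading entry of each axis
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import DistanceMatrix, GeoPoints, patristic_matrix

__all__ = ["Ordination", "pca", "pcoa", "patristic", "geodesic",
           "EARTH_RADIUS_M"]

#: mean Earth radius (m) for the spherical great-circle distance
EARTH_RADIUS_M = 6_371_008.8

_EIG_TOL = 1e-8


@dataclass
class Ordination:
    """Eigenvalues, row scores and (for PCA) variable loadings.

    ``correction_constant`` is the Cailliez constant c added to off-diagonal
    dissimilarities; 0 when the input was already Euclidean or no correction
    was requested.
    """

    eigenvalues: np.ndarray
    row_scores: pd.DataFrame
    col_loadings: pd.DataFrame | None
    total_inertia: float
    correction_constant: float = 0.0

    @property
    def axis_shares(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def summary(self) -> str:
        lines = [f"Ordination: {len(self.eigenvalues)} axes, "
                 f"total inertia {self.total_inertia:.4f}"]
        if self.correction_constant:
            lines.append(f"Cailliez correction constant c = "
                         f"{self.correction_constant:.6f}")
        for i, (ev, sh) in enumerate(zip(self.eigenvalues, self.axis_shares), 1):
            lines.append(f"axis {i:<2d} {ev:10.5f}  ({100 * sh:5.2f}%)")
            if i >= 10:
                break
        return "\n".join(lines)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    for k in range(vectors.shape[1]):
        nz = np.flatnonzero(np.abs(vectors[:, k]) > 1e-10)
        if nz.size and vectors[nz[0], k] < 0:
            vectors[:, k] *= -1
    return vectors


def pca(matrix, scale: bool = False) -> Ordination:
    """Principal component analysis with uniform row weights.

    ``matrix`` may be a DataFrame or array.  If ``scale`` is False the input
    is assumed already centred (and reduced if a correlation PCA is wanted,
    e.g. the output of :func:`integrotax.morphometrics.standardize`);
    with ``scale=True`` the matrix is centred and reduced here.
    """
    df = pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    n = X.shape[0]
    if scale:
        X = X - X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        zero = np.flatnonzero(sd < 1e-12)
        if zero.size:
            raise ValueError(
                f"zero-variance column(s): {[df.columns[i] for i in zero]}")
        X = X / sd
    else:
        X = X - X.mean(axis=0)
    C = X.T @ X / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    rank = min(n - 1, X.shape[1]) if n > 1 else 1
    axes = [f"axis{k + 1}" for k in range(rank)]
    scores = pd.DataFrame(X @ evecs[:, :rank], index=df.index, columns=axes)
    loadings = pd.DataFrame(evecs[:, :rank], index=df.columns, columns=axes)
    return Ordination(eigenvalues=evals[:rank], row_scores=scores,
                      col_loadings=loadings, total_inertia=float(evals.sum()))


# ---------------------------------------------------------------------------
# PCoA with Cailliez correction
# ---------------------------------------------------------------------------

def _gower(D2: np.ndarray) -> np.ndarray:
    """Double-centred -D^2/2 (Gower matrix)."""
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D2 @ J


def cailliez_constant(D: np.ndarray) -> float:
    """Smallest c such that D + c (off-diagonal) is Euclidean.

    c is the largest real eigenvalue of the 2n x 2n companion matrix
    ``[[0, 2*G(D^2)], [-I, -4*G(D)]]`` where G is Gower double-centring.
    """
    n = D.shape[0]
    B1 = _gower(D * D)
    B2 = _gower(D)
    Z = np.zeros((n, n))
    M = np.block([[Z, 2.0 * B1], [-np.eye(n), -4.0 * B2]])
    ev = np.linalg.eigvals(M)
    real = ev.real[np.abs(ev.imag) < 1e-8 * (1 + np.abs(ev.real))]
    return float(max(real.max(), 0.0))


def pcoa(D: DistanceMatrix, correction: str = "none") -> Ordination:
    """Principal coordinate analysis of a dissimilarity matrix.

    With ``correction='cailliez'`` and negative eigenvalues present, the
    smallest constant c making the configuration Euclidean is added to every
    off-diagonal dissimilarity and the analysis is recomputed; the returned
    row scores then reproduce ``D[i,j] + c`` pairwise (within tolerance).
    Eigenvalues within tolerance of zero are truncated to zero and axes are
    reported up to rank n - 1.
    """
    if correction not in ("none", "cailliez"):
        raise ValueError(f"unknown correction {correction!r}")
    Dm = D.D
    if np.isnan(Dm).any():
        raise ValueError("distance matrix has missing entries")
    c = 0.0
    B = _gower(Dm * Dm)
    evals = np.linalg.eigvalsh(B)
    if correction == "cailliez" and evals.min() < -_EIG_TOL * max(1.0, evals.max()):
        c = cailliez_constant(Dm)
        Dm = Dm + c
        np.fill_diagonal(Dm, 0.0)
        B = _gower(Dm * Dm)
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n = len(D)
    scale = max(1.0, abs(evals[0]))
    keep = evals > _EIG_TOL * scale
    keep[n - 1:] = False       # at most n-1 axes
    evals_k = evals[keep]
    vecs = _fix_signs(evecs[:, keep])
    coords = vecs * np.sqrt(evals_k)
    axes = [f"axis{k + 1}" for k in range(coords.shape[1])]
    scores = pd.DataFrame(coords, index=D.labels, columns=axes)
    # inertia convention: uniform row weights 1/n
    return Ordination(eigenvalues=evals_k / n, row_scores=scores,
                      col_loadings=None, total_inertia=float(evals_k.sum() / n),
                      correction_constant=c)


def patristic(tree) -> DistanceMatrix:
    """Tip-to-tip sum of branch lengths (delegates to the tree container)."""
    return patristic_matrix(tree)


def geodesic(points: GeoPoints) -> DistanceMatrix:
    """Great-circle (haversine) pairwise distances in meters on a sphere of
    mean Earth radius."""
    lat = np.radians(points.latitude)
    lon = np.radians(points.longitude)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2.0) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2)
    a = np.clip(a, 0.0, 1.0)
    D = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(list(points.ids), D)
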