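"""Multi-table coupling: the RV coefficient with its permutation test, and
multiple co-inertia analysis (MCOA).

RV coefficient
--------------
For two column-centred tables X, Y describing the same objects,

    RV = trace(XX'YY') / sqrt(trace((XX')^2) * trace((YY')^2))

is a matrix correlation in [0, 1]; the permutation test shuffles the rows of
one table and recomputes RV.

MCOA
----
Given K centred tables X_k (same n objects), axis r finds a unit-variance
auxiliary ("synthetic") variable v and per-table unit-norm loading vectors u_k
maximizing the weighted sum of squared covariances

    sum_k w_k Cov^2(X_k u_k, v),        Cov(a, b) = a'b / n.

The solution v is the leading eigenvector of (1/n) sum_k w_k X_k X_k'
(scaled to variance 1), with u_k proportional to X_k' v.  Before each
subsequent axis every table is deflated by orthogonal projection of its
columns onto the complement of its own previous (normed) scores, and the
summed operator is restricted to the orthocomplement of the previous
synthetic variables, so compromise axes are mutually orthonormal in the
1/n row-weight metric.

The per-axis decomposition reported for each table:

* ``cov2``  — w_k Cov^2(X_k u_k, v), the table's contribution to the
  maximized criterion (sums over tables to the pseudo-eigenvalue);
* ``cos2``  — squared correlation between the table score and v;
* ``coinertia`` — Var(X_k u_k), the table inertia projected on its axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["rv", "rv_test", "RVTestResult", "MCOA", "MCOAResults", "mcoa"]


def _centered(X) -> np.ndarray:
    X = np.asarray(pd.DataFrame(X).to_numpy(), dtype=float)
    return X - X.mean(axis=0)


def rv(X, Y) -> float:
    """RV matrix correlation between two object-configurations."""
    X, Y = _centered(X), _centered(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("tables must describe the same objects (row mismatch)")
    Wx = X @ X.T
    Wy = Y @ Y.T
    nx = np.sqrt(np.sum(Wx * Wx))
    ny = np.sqrt(np.sum(Wy * Wy))
    if nx == 0 or ny == 0:
        raise ValueError("all-zero table")
    return float(np.sum(Wx * Wy) / (nx * ny))


@dataclass
class RVTestResult:
    rv: float
    perm_values: np.ndarray
    p_value: float

    @property
    def n_perm(self) -> int:
        return len(self.perm_values)

    def summary(self) -> str:
        return (f"RV = {self.rv:.4f}, permutation p = {self.p_value:.4g} "
                f"({self.n_perm} permutations)")


def rv_test(X, Y, n_perm: int = 9999, seed: int | None = None) -> RVTestResult:
    """Monte Carlo permutation test of the RV coefficient (rows of Y shuffled;
    add-one p-value, ties counted as exceedances)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, Y = _centered(X), _centered(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("row mismatch")
    observed = rv(X, Y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = np.empty(n_perm)
    Wx = X @ X.T
    nx = np.sqrt(np.sum(Wx * Wx))
    Wy = Y @ Y.T
    ny = np.sqrt(np.sum(Wy * Wy))
    for b in range(n_perm):
        p = rng.permutation(n)
        perm[b] = np.sum(Wx * Wy[np.ix_(p, p)]) / (nx * ny)
    p_value = (np.count_nonzero(perm >= observed - 1e-12) + 1) / (n_perm + 1)
    return RVTestResult(observed, perm, p_value)


# ---------------------------------------------------------------------------
# MCOA
# ---------------------------------------------------------------------------

@dataclass
class MCOAResults:
    """Fitted multiple co-inertia analysis (the shape of a compromise table).

    Attributes
    ----------
    pseudo_eigenvalues : per-axis maximized criterion value.
    compromise_scores : objects x axes synthetic variables (variance 1 each).
    table_scores : dict table -> objects x axes scores X_k u_k.
    cos2, cov2, coinertia : tables x axes decomposition (see module docstring).
    """

    pseudo_eigenvalues: np.ndarray
    compromise_scores: pd.DataFrame
    table_scores: dict[str, pd.DataFrame]
    cos2: pd.DataFrame
    cov2: pd.DataFrame
    coinertia: pd.DataFrame
    table_inertia: pd.DataFrame        # per-table per-axis separate-PCA inertia
    weights: dict[str, float]

    def summary(self) -> str:
        lines = ["Multiple co-inertia analysis",
                 "=" * 40,
                 "pseudo-eigenvalues: "
                 + "  ".join(f"{v:.5f}" for v in self.pseudo_eigenvalues),
                 "", "Cov2 (contribution to the compromise):",
                 self.cov2.round(4).to_string(),
                 "", "Cos2 (correlation table score ~ synthetic variable):",
                 self.cos2.round(4).to_string(),
                 "", "Co-inertia (projected table inertia):",
                 self.coinertia.round(4).to_string()]
        return "\n".join(lines)


class MCOA:
    """Multiple co-inertia analysis model over K row-conformable tables.

    Parameters
    ----------
    tables : mapping name -> DataFrame/array
        Centred tables with identical object rows (same order). Tables are
        centred here if needed; scaling is the caller's choice (standardized
        morphometrics; PCoA coordinates as-is).
    weights : None | 'uniform' | 'inverse_first_eigenvalue' | 'inverse_total_inertia' | mapping
        Table weights in the criterion; default uniform (1 per table).
    """

    def __init__(self, tables: dict, weights="uniform") -> None:
        if len(tables) < 1:
            raise ValueError("at least one table required")
        self.names = list(tables)
        self.index = pd.DataFrame(tables[self.names[0]]).index
        self.X = {}
        for name in self.names:
            df = pd.DataFrame(tables[name])
            if df.shape[0] != len(self.index):
                raise ValueError(f"table {name!r} row count mismatch")
            self.X[name] = _centered(df)
        self.n = len(self.index)
        self.weights = self._resolve_weights(weights)

    def _resolve_weights(self, weights) -> dict[str, float]:
        if isinstance(weights, dict):
            return {k: float(weights[k]) for k in self.names}
        if weights in (None, "uniform"):
            return {k: 1.0 for k in self.names}
        out = {}
        for k in self.names:
            X = self.X[k]
            ev = np.linalg.eigvalsh(X.T @ X / self.n)
            if weights == "inverse_first_eigenvalue":
                out[k] = 1.0 / ev.max()
            elif weights == "inverse_total_inertia":
                out[k] = 1.0 / ev.sum()
            else:
                raise ValueError(f"unknown weight scheme {weights!r}")
        return out

    def fit(self, n_axes: int = 2) -> MCOAResults:
        n = self.n
        Xk = {k: self.X[k].copy() for k in self.names}
        w = self.weights
        V = np.zeros((n, 0))                 # unit-norm synthetic variables
        pseudo, comp_cols = [], []
        scores = {k: [] for k in self.names}
        cos2 = {k: [] for k in self.names}
        cov2 = {k: [] for k in self.names}
        coin = {k: [] for k in self.names}

        max_rank = min(n - 1, sum(self.X[k].shape[1] for k in self.names))
        n_axes = min(n_axes, max_rank)
        for r in range(n_axes):
            M = sum(w[k] * (Xk[k] @ Xk[k].T) for k in self.names) / n
            P = np.eye(n) - V @ V.T
            M = P @ M @ P
            evals, evecs = np.linalg.eigh(M)
            lead = np.argmax(evals)
            # criterion value: vt' M vt with M already carrying the 1/n scaling
            lam = evals[lead]
            if lam < 1e-12:
                break                         # rank exhausted
            vt = evecs[:, lead]
            vt = vt - V @ (V.T @ vt)
            vt /= np.linalg.norm(vt)
            v = vt * np.sqrt(n)              # variance-1 synthetic variable
            # axis sign: positive covariance with the first table's score
            pseudo.append(lam)
            first = True
            for k in self.names:
                u = Xk[k].T @ vt
                norm_u = np.linalg.norm(u)
                if norm_u > 1e-12:
                    u = u / norm_u
                s = Xk[k] @ u
                if first:
                    if s @ v < 0:
                        v = -v
                        vt = -vt
                        u, s = -u, -s
                    first = False
                elif s @ v < 0:
                    u, s = -u, -s
                cov = (s @ v) / n
                var_s = (s @ s) / n
                cov2[k].append(w[k] * cov ** 2)
                cos2[k].append((cov ** 2 / var_s) if var_s > 1e-15 else 0.0)
                coin[k].append(var_s)
                scores[k].append(s)
                # deflate the table on its own normed score
                if var_s > 1e-15:
                    sn = s / np.linalg.norm(s)
                    Xk[k] = Xk[k] - np.outer(sn, sn @ Xk[k])
            comp_cols.append(v)
            V = np.hstack([V, vt[:, None]])

        axes = [f"axis{r + 1}" for r in range(len(pseudo))]
        compromise = pd.DataFrame(np.column_stack(comp_cols), index=self.index,
                                  columns=axes)
        table_scores = {k: pd.DataFrame(np.column_stack(scores[k]),
                                        index=self.index, columns=axes)
                        for k in self.names}
        sep_inertia = {}
        for k in self.names:
            ev = np.sort(np.linalg.eigvalsh(self.X[k].T @ self.X[k] / n))[::-1]
            sep_inertia[k] = ev[:len(axes)] if ev.size >= len(axes) \
                else np.pad(ev, (0, len(axes) - ev.size))

        def frame(d):
            return pd.DataFrame(d, index=axes).T.loc[self.names]

        return MCOAResults(
            pseudo_eigenvalues=np.asarray(pseudo),
            compromise_scores=compromise,
            table_scores=table_scores,
            cos2=frame(cos2), cov2=frame(cov2), coinertia=frame(coin),
            table_inertia=frame(sep_inertia),
            weights=dict(w))


def mcoa(tables: dict, weights="uniform", n_axes: int = 2) -> MCOAResults:
    """Convenience wrapper: ``MCOA(tables, weights).fit(n_axes)``."""
    return MCOA(tables, weights).fit(n_axes=n_axes)
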