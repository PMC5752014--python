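"""Morphometric preprocessing and between-group analysis (BGA).

The workflow mirrors standard multivariate morphometrics for allometric data:

1. juveniles (SL below a threshold) are excluded to limit allometric bias;
2. missing cells (broken fin rays etc.) are imputed per population by least
   squares regression of the variable on standard length (SL);
3. morphometric variables are size-standardized as ``log(value / SL)``,
   ``log(SL)`` itself is retained, meristic counts enter raw, and every
   column is centred and reduced (correlation-PCA convention: each column has
   mean 0 and population variance 1, so the total inertia equals the column
   count);
4. a between-group analysis — the PCA of the size-weighted group-mean rows —
   measures the fraction of total inertia lying between groups, and a Monte
   Carlo permutation test of that fraction (group labels shuffled) tests the
   null of no group structure.

``BetweenGroupAnalysis`` is the model object; ``fit`` returns ``BGAResults``
with eigenvalues, scores, loadings, the permutation null distribution and the
add-one permutation p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import MorphoTable

__all__ = ["filter_juveniles", "impute_missing", "standardize",
           "BetweenGroupAnalysis", "BGAResults", "bga"]


def filter_juveniles(table: MorphoTable, min_sl: float = 20.0) -> MorphoTable:
    """Drop specimens with SL strictly below ``min_sl`` (mm).

    Specimens at exactly ``min_sl`` are retained. The removed ids are recorded
    in ``result.meta['removed_ids']``.
    """
    keep = table.sl >= min_sl
    if not keep.any():
        raise ValueError(f"no specimens with SL >= {min_sl}")
    removed = table.sl.index[~keep].tolist()
    out = table.subset(table.sl.index[keep])
    out.meta["removed_ids"] = removed
    return out


def impute_missing(table: MorphoTable) -> MorphoTable:
    """Fill missing cells by within-group least squares on SL.

    For every (group, variable) pair with a missing cell, a simple linear
    regression of the variable on SL is fitted to the group's observed rows
    and the fitted value at the specimen's SL replaces the missing cell.
    A group with fewer than two observed rows for a needed variable is an
    error — there is no defensible fallback for a regression on one point.
    """
    values = table.values.copy()
    sl = table.sl
    for group, idx in table.group_labels.groupby(table.group_labels).groups.items():
        block = values.loc[idx]
        for col in block.columns[block.isna().any()]:
            obs = block[col].notna()
            if obs.sum() < 2:
                raise ValueError(
                    f"cannot impute {col!r} in group {group!r}: "
                    f"only {int(obs.sum())} observed value(s)")
            x = sl.loc[idx][obs].to_numpy()
            y = block.loc[obs, col].to_numpy()
            if np.ptp(x) < 1e-12:
                # degenerate SL spread: fall back to the group mean (slope 0)
                slope, intercept = 0.0, float(y.mean())
            else:
                slope, intercept = np.polyfit(x, y, 1)
            miss = block.index[block[col].isna()]
            fitted = intercept + slope * sl.loc[miss]
            if table.variable_kind[col] == "meristic":
                # counts live on a half-unit grid; snap the fitted value back
                fitted = np.round(fitted * 2) / 2
            values.loc[miss, col] = fitted
    return MorphoTable(values, table.group_labels.copy(),
                       dict(table.variable_kind), dict(table.meta))


def standardize(table: MorphoTable, log_base: float = math.e) -> pd.DataFrame:
    """Size-standardize, log-transform, then centre and reduce.

    Morphometric columns become ``log(value / SL)``; the SL column becomes
    ``log(SL)`` and is retained as a size variable; meristic columns are used
    raw. Every column is then centred to mean 0 and scaled to population
    (1/n) standard deviation 1, so the total inertia of a subsequent
    correlation PCA equals the number of columns.
    """
    if table.n_missing:
        raise ValueError("standardize requires an imputed table (missing cells remain)")
    sl = table.sl.to_numpy(dtype=float)
    out = {}
    logb = math.log(log_base)
    for col in table.variable_names:
        kind = table.variable_kind[col]
        v = table.values[col].to_numpy(dtype=float)
        if kind == "SL":
            if np.any(v <= 0):
                raise ValueError("nonpositive SL")
            out[col] = np.log(v) / logb
        elif kind in ("morphometric_SL", "morphometric_HL"):
            ratio = v / sl
            if np.any(ratio <= 0):
                raise ValueError(f"nonpositive morphometric value in {col!r}")
            out[col] = np.log(ratio) / logb
        else:  # meristic
            out[col] = v
    df = pd.DataFrame(out, index=table.values.index)
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    zero = sd.index[sd < 1e-12].tolist()
    if zero:
        raise ValueError(f"zero-variance column(s) after transformation: {zero}")
    return (df - mean) / sd


# ---------------------------------------------------------------------------
# BGA
# ---------------------------------------------------------------------------

def _between_inertia(X: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Between-class inertia with uniform row weights 1/n: sum over groups of
    (n_g / n) * ||group mean||^2 of the centred-scaled matrix."""
    n = X.shape[0]
    sums = np.zeros((n_groups, X.shape[1]))
    np.add.at(sums, codes, X)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    means = sums / counts[:, None]
    return float(np.sum(counts / n * np.einsum("ij,ij->i", means, means)))


@dataclass
class BGAResults:
    """Fitted between-group analysis.

    ``ratio`` is the between-group share of total inertia (X_obs of the
    permutation test); ``eigenvalues`` are the per-axis between-class
    inertias, which sum to ``ratio * total_inertia``.
    """

    ratio: float
    total_inertia: float
    eigenvalues: np.ndarray
    group_scores: pd.DataFrame
    specimen_scores: pd.DataFrame
    variable_loadings: pd.DataFrame
    perm_distribution: np.ndarray | None
    p_value: float | None
    n_perm: int

    @property
    def between_inertia(self) -> float:
        return self.ratio * self.total_inertia

    def axis_share(self, axes=(0, 1)) -> float:
        """Share of between-class inertia carried by the given axes."""
        ev = self.eigenvalues
        return float(ev[list(axes)].sum() / ev.sum())

    def summary(self) -> str:
        lines = ["Between-group analysis",
                 "=" * 40,
                 f"total inertia          {self.total_inertia:.4f}",
                 f"between-group inertia  {self.between_inertia:.5f}",
                 f"ratio (X_obs)          {self.ratio:.7f}"]
        shares = self.eigenvalues / self.eigenvalues.sum()
        for i, (ev, sh) in enumerate(zip(self.eigenvalues, shares), start=1):
            if sh < 1e-12:
                break
            lines.append(f"axis {i:<2d} eigenvalue {ev:.5f}  ({100 * sh:.2f}% of "
                         "between-class inertia)")
        if self.p_value is not None:
            lines.append(f"permutation test: {self.n_perm} permutations, "
                         f"p = {self.p_value:.4g}")
        return "\n".join(lines)


class BetweenGroupAnalysis:
    """PCA of size-weighted group means of a centred-scaled specimen matrix.

    Parameters
    ----------
    X : DataFrame
        Output of :func:`standardize` (columns mean 0, population variance 1).
    groups : Series or array
        Group label per specimen, aligned with ``X`` rows.
    """

    def __init__(self, X: pd.DataFrame, groups) -> None:
        self.X = X
        groups = pd.Series(np.asarray(groups), index=X.index) \
            if not isinstance(groups, pd.Series) else groups.reindex(X.index)
        if groups.isna().any():
            raise ValueError("group label missing for some specimens")
        self.groups = groups
        self.group_names, self.codes = np.unique(groups.to_numpy(), return_inverse=True)
        if (np.bincount(self.codes) == 0).any():
            raise ValueError("empty group")

    def fit(self, n_perm: int = 9999, seed: int | None = None) -> BGAResults:
        X = self.X.to_numpy(dtype=float)
        n, p = X.shape
        g = len(self.group_names)
        counts = np.bincount(self.codes, minlength=g).astype(float)
        weights = counts / n

        sums = np.zeros((g, p))
        np.add.at(sums, self.codes, X)
        means = sums / counts[:, None]

        # eigen-analysis of the weighted between-class cross-product matrix
        B = (means * weights[:, None]).T @ means
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.clip(evals, 0.0, None)
        # sign convention: first non-negligible loading of each axis positive
        for k in range(evecs.shape[1]):
            nz = np.flatnonzero(np.abs(evecs[:, k]) > 1e-10)
            if nz.size and evecs[nz[0], k] < 0:
                evecs[:, k] *= -1

        total_inertia = float(np.sum(X * X) / n)   # == p for a reduced table
        between = float(evals.sum())
        ratio = between / total_inertia

        n_axes = min(g - 1, p) if g > 1 else 1
        n_axes = max(n_axes, 1)
        axes = [f"axis{k + 1}" for k in range(n_axes)]
        U = evecs[:, :n_axes]
        group_scores = pd.DataFrame(means @ U, index=self.group_names, columns=axes)
        specimen_scores = pd.DataFrame(X @ U, index=self.X.index, columns=axes)
        loadings = pd.DataFrame(U, index=self.X.columns, columns=axes)

        perm_dist = None
        p_value = None
        if n_perm and n_perm > 0:
            rng = np.random.default_rng(seed)
            perm_dist = np.empty(n_perm)
            codes = self.codes
            for b in range(n_perm):
                perm_dist[b] = _between_inertia(X[rng.permutation(n)], codes, g) \
                    / total_inertia
            # add-one estimator; ties count as exceedances (conservative)
            p_value = (np.count_nonzero(perm_dist >= ratio - 1e-12) + 1) / (n_perm + 1)

        return BGAResults(ratio=ratio, total_inertia=total_inertia,
                          eigenvalues=evals[:n_axes], group_scores=group_scores,
                          specimen_scores=specimen_scores,
                          variable_loadings=loadings,
                          perm_distribution=perm_dist, p_value=p_value,
                          n_perm=n_perm if perm_dist is not None else 0)


def bga(X: pd.DataFrame, groups, n_perm: int = 9999,
        seed: int | None = None) -> BGAResults:
    """Convenience wrapper: ``BetweenGroupAnalysis(X, groups).fit(...)``."""
    return BetweenGroupAnalysis(X, groups).fit(n_perm=n_perm, seed=seed)
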