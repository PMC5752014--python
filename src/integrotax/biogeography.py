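"""Dispersal-extinction-cladogenesis (DEC) range evolution with optional
founder-event ("jump") speciation, maximum-likelihood fitting, ancestral-range
marginals, and the DEC vs DEC+j likelihood-ratio test.

Model
-----
A species range is a nonempty subset of discrete areas, capped at
``max_range_size``; the empty (null) range is kept in the state space as an
absorbing state. Along branches, ranges evolve by a continuous-time Markov
chain with per-event rates

* expansion  ``R -> R + {b}``  at rate ``|R| * d``  (uniform area adjacency),
* contraction ``R -> R - {a}`` at rate ``e`` (size-1 ranges contract to null).

At every bifurcation a cladogenetic event splits the ancestor range into an
ordered daughter pair. Allowed events and per-pair base weights:

* sympatry (``|R| = 1``; both daughters = R) — weight y,
* subset sympatry (one daughter = R, the other a single area inside R) — s,
* vicariance (disjoint split with one size-1 daughter) — v,
* jump / founder (one daughter = R, the other a single area outside R) — j,

with ``y = s = v = (3 - j)/3`` so that j = 0 recovers plain DEC; ordered-pair
probabilities are the weights normalized per ancestor state. The likelihood
is computed by Felsenstein pruning with matrix exponentials on branches and
the cladogenetic mixture at internal nodes; the root state prior is uniform
over non-null states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .tables import TipRangeTable

__all__ = ["RangeStateSpace", "DECParams", "build_state_space",
           "build_rate_matrix", "clado_event_weights", "CladoStructure",
           "likelihood", "DECModel", "DECResults", "fit_ml", "lrt", "LRTResult"]

# optimizer bounds
D_BOUNDS = (1e-6, 5.0)
E_BOUNDS = (1e-6, 5.0)
J_BOUNDS = (0.0, 2.99999)


@dataclass(frozen=True)
class DECParams:
    """Rates of range expansion (d), contraction (e) and founder weight (j)."""

    d: float
    e: float
    j: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("d and e must be nonnegative")
        if not (0 <= self.j < 3):
            raise ValueError("j must be in [0, 3)")


class RangeStateSpace:
    """All nonempty subsets of the areas up to ``max_range_size``, plus the
    null range at index 0. States are canonically ordered by (size, areas)."""

    def __init__(self, areas, max_range_size: int) -> None:
        areas = list(areas)
        if max_range_size < 1:
            raise ValueError("max_range_size must be >= 1")
        if max_range_size > len(areas):
            raise ValueError("max_range_size exceeds the number of areas")
        if len(set(areas)) != len(areas):
            raise ValueError("duplicate area codes")
        self.areas = areas
        self.max_range_size = max_range_size
        states: list[frozenset] = [frozenset()]
        for size in range(1, max_range_size + 1):
            for combo in itertools.combinations(areas, size):
                states.append(frozenset(combo))
        self.states = states
        self.index = {s: i for i, s in enumerate(states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_nonnull(self) -> int:
        return len(self.states) - 1

    def state_label(self, i: int) -> str:
        s = self.states[i]
        return "+".join(sorted(s)) if s else "null"

    def __repr__(self) -> str:
        return (f"RangeStateSpace({len(self.areas)} areas, "
                f"max {self.max_range_size}, {self.n_nonnull} non-null states)")


def build_state_space(areas, max_range_size: int) -> RangeStateSpace:
    return RangeStateSpace(areas, max_range_size)


def build_rate_matrix(space: RangeStateSpace, params: DECParams) -> np.ndarray:
    """Anagenetic generator Q over the full state space (null absorbing)."""
    S = space.n_states
    Q = np.zeros((S, S))
    for i, rng in enumerate(space.states):
        if not rng:
            continue                      # null range is absorbing
        if len(rng) < space.max_range_size:
            for b in space.areas:
                if b not in rng:
                    Q[i, space.index[rng | {b}]] = len(rng) * params.d
        for a in rng:
            Q[i, space.index[rng - {a}]] = params.e
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


# ---------------------------------------------------------------------------
# cladogenesis
# ---------------------------------------------------------------------------

# event categories
_SYMPATRY, _SUBSET, _VICARIANCE, _JUMP = 0, 1, 2, 3


def _enumerate_pairs(space: RangeStateSpace, anc: frozenset):
    """Yield (left, right, category) for every allowed ordered daughter pair."""
    areas = set(space.areas)
    if len(anc) == 1:
        yield anc, anc, _SYMPATRY
        for b in sorted(areas - anc):
            yield anc, frozenset({b}), _JUMP
            yield frozenset({b}), anc, _JUMP
    else:
        seen = set()
        for a in sorted(anc):
            single = frozenset({a})
            yield anc, single, _SUBSET
            yield single, anc, _SUBSET
            rest = anc - single
            # for |anc| = 2 the mirror split of the other area coincides;
            # emit each ordered vicariance pair exactly once
            for pair in ((single, rest), (rest, single)):
                if pair not in seen:
                    seen.add(pair)
                    yield pair[0], pair[1], _VICARIANCE
        for b in sorted(areas - anc):
            single = frozenset({b})
            yield anc, single, _JUMP
            yield single, anc, _JUMP


def clado_event_weights(anc: frozenset, space: RangeStateSpace,
                        params: DECParams) -> dict:
    """Probability of each ordered daughter pair given the ancestor range."""
    anc = frozenset(anc)
    if not anc:
        raise ValueError("empty ancestor range")
    ysv = (3.0 - params.j) / 3.0
    weights = {}
    for left, right, cat in _enumerate_pairs(space, anc):
        w = params.j if cat == _JUMP else ysv
        weights[(left, right)] = weights.get((left, right), 0.0) + w
    total = sum(weights.values())
    return {pair: w / total for pair, w in weights.items()}


class CladoStructure:
    """Flattened cladogenetic pair lists for vectorized pruning.

    Weight categories are parameter-independent, so the structure is built
    once per state space and re-weighted per j.
    """

    def __init__(self, space: RangeStateSpace) -> None:
        self.space = space
        anc_idx, left_idx, right_idx, cat = [], [], [], []
        for i, rng in enumerate(space.states):
            if not rng:
                continue
            for left, right, c in _enumerate_pairs(space, rng):
                anc_idx.append(i)
                left_idx.append(space.index[left])
                right_idx.append(space.index[right])
                cat.append(c)
        self.anc = np.asarray(anc_idx, dtype=np.intp)
        self.left = np.asarray(left_idx, dtype=np.intp)
        self.right = np.asarray(right_idx, dtype=np.intp)
        self.cat = np.asarray(cat, dtype=np.int8)

    def probabilities(self, j: float) -> np.ndarray:
        """Per-ordered-pair probability under founder weight j."""
        ysv = (3.0 - j) / 3.0
        w = np.where(self.cat == _JUMP, j, ysv)
        norm = np.zeros(self.space.n_states)
        np.add.at(norm, self.anc, w)
        return w / norm[self.anc]

    def combine(self, prob: np.ndarray, down_left: np.ndarray,
                down_right: np.ndarray) -> np.ndarray:
        """Conditional likelihood of an internal node from its daughters'
        branch-bottom likelihood vectors."""
        contrib = prob * down_left[self.left] * down_right[self.right]
        return np.bincount(self.anc, weights=contrib,
                           minlength=self.space.n_states)

    def spread(self, prob: np.ndarray, outside_node: np.ndarray,
               down_sib: np.ndarray, to_child: str) -> np.ndarray:
        """Outside weight passed to one daughter (before its branch)."""
        own = self.left if to_child == "left" else self.right
        sib = self.right if to_child == "left" else self.left
        contrib = prob * outside_node[self.anc] * down_sib[sib]
        return np.bincount(own, weights=contrib,
                           minlength=self.space.n_states)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _Pruner:
    """Caches tree traversal order, tip state vectors and per-branch
    transition matrices for repeated likelihood evaluations."""

    def __init__(self, tree, tip_ranges: TipRangeTable,
                 space: RangeStateSpace) -> None:
        for node in tree.preorder_node_iter():
            if node.num_child_nodes() not in (0, 2):
                raise ValueError("tree must be strictly bifurcating "
                                 "(resolve polytomies first)")
        tip_ranges.check_covers(tree)
        self.tree = tree
        self.space = space
        self.clado = CladoStructure(space)
        self.postorder = list(tree.postorder_node_iter())
        self.tip_state = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            rng = tip_ranges.ranges[label]
            if rng not in space.index:
                raise ValueError(f"tip {label!r} range {sorted(rng)} exceeds "
                                 f"max_range_size {space.max_range_size}")
            v = np.zeros(space.n_states)
            v[space.index[rng]] = 1.0
            self.tip_state[id(leaf)] = v
        # per-branch-length expm cache for the CURRENT parameter values only;
        # keeping caches for every optimizer iterate would exhaust memory
        self._cache_key: tuple | None = None
        self._expm_cache: dict[float, np.ndarray] = {}

    def _transition(self, Q_key, Q: np.ndarray, t: float) -> np.ndarray:
        if Q_key != self._cache_key:
            self._cache_key = Q_key
            self._expm_cache = {}
        P = self._expm_cache.get(t)
        if P is None:
            P = expm(Q * t)
            self._expm_cache[t] = P
        return P

    def loglik(self, params: DECParams, return_state=False):
        space = self.space
        Q = build_rate_matrix(space, params)
        Q_key = (params.d, params.e)
        prob = self.clado.probabilities(params.j)
        log_scale = 0.0
        CL: dict[int, np.ndarray] = {}
        down: dict[int, np.ndarray] = {}

        for node in self.postorder:
            if node.is_leaf():
                CL[id(node)] = self.tip_state[id(node)]
            else:
                ca, cb = node.child_nodes()
                da = self._transition(Q_key, Q, ca.edge.length or 0.0) @ CL[id(ca)]
                db = self._transition(Q_key, Q, cb.edge.length or 0.0) @ CL[id(cb)]
                down[id(ca)], down[id(cb)] = da, db
                cl = self.clado.combine(prob, da, db)
                m = cl.max()
                if m > 0:
                    cl = cl / m
                    log_scale += np.log(m)
                CL[id(node)] = cl

        root = self.tree.seed_node
        pi = np.zeros(space.n_states)
        pi[1:] = 1.0 / space.n_nonnull
        total = float(pi @ CL[id(root)])
        lnL = -np.inf if total <= 0 else np.log(total) + log_scale
        if return_state:
            return lnL, {"CL": CL, "down": down, "prob": prob,
                         "Q": Q, "Q_key": Q_key, "pi": pi}
        return lnL

    def node_marginals(self, params: DECParams) -> pd.DataFrame:
        """Marginal ancestral-state probabilities at every internal node
        (state immediately before cladogenesis), by an outside pass."""
        lnL, st = self.loglik(params, return_state=True)
        if not np.isfinite(lnL):
            raise ValueError("zero likelihood; marginals undefined")
        space, clado = self.space, self.clado
        CL, down, prob = st["CL"], st["down"], st["prob"]
        outside: dict[int, np.ndarray] = {id(self.tree.seed_node): st["pi"]}
        rows, labels = [], []
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            out_v = outside[id(node)]
            marg = out_v * CL[id(node)]
            total = marg.sum()
            rows.append(marg / total)
            labels.append(node.label or f"nd{len(labels)}")
            ca, cb = node.child_nodes()
            for child, sib, side in ((ca, cb, "left"), (cb, ca, "right")):
                g = clado.spread(prob, out_v, down[id(sib)], side)
                P = self._transition(st["Q_key"], st["Q"],
                                     child.edge.length or 0.0)
                o = g @ P
                m = o.max()
                outside[id(child)] = o / m if m > 0 else o
        cols = [space.state_label(i) for i in range(space.n_states)]
        return pd.DataFrame(rows, index=labels, columns=cols)


def likelihood(tree, tip_ranges: TipRangeTable, space: RangeStateSpace,
               params: DECParams) -> float:
    """Log-likelihood of tip ranges under DEC(+j); -inf when impossible."""
    return _Pruner(tree, tip_ranges, space).loglik(params)


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

@dataclass
class DECResults:
    """Fitted DEC or DEC+j model."""

    model: str
    params: DECParams
    lnL: float
    n_params: int
    converged: bool
    start_values: list = field(default_factory=list, repr=False)
    _pruner: "_Pruner" = field(default=None, repr=False)
    _marginals: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def node_marginals(self) -> pd.DataFrame:
        """Per-internal-node posterior probability over range states
        (computed lazily, cached)."""
        if self._marginals is None:
            self._marginals = self._pruner.node_marginals(self.params)
        return self._marginals

    def summary(self) -> str:
        p = self.params
        lines = [f"{self.model} fit", "=" * 30,
                 f"lnL       {self.lnL:.4f}",
                 f"numparams {self.n_params}",
                 f"d         {p.d:.5f}",
                 f"e         {p.e:.5f}"]
        if self.model.upper() != "DEC":
            lines.append(f"j         {p.j:.5f}")
        if not self.converged:
            lines.append("WARNING: optimizer did not report convergence")
        return "\n".join(lines)


class DECModel:
    """Maximum-likelihood DEC / DEC+j model over a tree and tip ranges.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted, strictly bifurcating, with branch lengths.
    tip_ranges : TipRangeTable
    space : RangeStateSpace
    model : 'DEC' or 'DEC+J'
        'DEC' pins j = 0; 'DEC+J' frees it.
    """

    def __init__(self, tree, tip_ranges: TipRangeTable,
                 space: RangeStateSpace, model: str = "DEC") -> None:
        model = model.upper()
        if model in ("DECJ", "DEC_J", "DEC-J"):
            model = "DEC+J"
        if model not in ("DEC", "DEC+J"):
            raise ValueError("model must be 'DEC' or 'DEC+J'")
        self.model = model
        self.space = space
        self.pruner = _Pruner(tree, tip_ranges, space)

    def loglike(self, params: DECParams) -> float:
        return self.pruner.loglik(params)

    def _starts(self, n_starts: int, seed) -> np.ndarray:
        """Seeded Latin-grid starting points (log-uniform in d, e)."""
        rng = np.random.default_rng(seed)
        k = 3 if self.model == "DEC+J" else 2
        # stratified samples per dimension, independently shuffled
        u = (np.arange(n_starts)[:, None] + rng.random((n_starts, k))) / n_starts
        for col in range(k):
            u[:, col] = u[rng.permutation(n_starts), col]
        lo_d, hi_d = np.log(D_BOUNDS[0]), np.log(D_BOUNDS[1])
        lo_e, hi_e = np.log(E_BOUNDS[0]), np.log(E_BOUNDS[1])
        starts = np.empty((n_starts, k))
        starts[:, 0] = np.exp(lo_d + u[:, 0] * (hi_d - lo_d))
        starts[:, 1] = np.exp(lo_e + u[:, 1] * (hi_e - lo_e))
        if k == 3:
            starts[:, 2] = u[:, 2] * 1.0    # j starts in [0, 1)
        return starts

    def fit(self, n_starts: int = 5, seed: int | None = None) -> DECResults:
        free_j = self.model == "DEC+J"
        bounds = [D_BOUNDS, E_BOUNDS] + ([J_BOUNDS] if free_j else [])

        def negll(x):
            p = DECParams(x[0], x[1], x[2] if free_j else 0.0)
            ll = self.pruner.loglik(p)
            return 1e10 if not np.isfinite(ll) else -ll

        best = None
        starts = self._starts(n_starts, seed)
        for x0 in starts:
            res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        x = best.x
        params = DECParams(x[0], x[1], x[2] if free_j else 0.0)
        return DECResults(model=self.model, params=params, lnL=-best.fun,
                          n_params=3 if free_j else 2,
                          converged=bool(best.success),
                          start_values=starts.tolist(),
                          _pruner=self.pruner)


def fit_ml(tree, tip_ranges: TipRangeTable, space: RangeStateSpace,
           model: str = "DEC", n_starts: int = 5,
           seed: int | None = None) -> DECResults:
    """Convenience wrapper: ``DECModel(...).fit(...)``."""
    return DECModel(tree, tip_ranges, space, model=model).fit(
        n_starts=n_starts, seed=seed)


@dataclass
class LRTResult:
    D: float
    df: int
    p_value: float

    def summary(self) -> str:
        return f"LRT: D = {self.D:.4f}, df = {self.df}, p = {self.p_value:.3g}"


def lrt(fit_dec: DECResults, fit_decj: DECResults) -> LRTResult:
    """Likelihood-ratio test of DEC+j against nested DEC (df = 1)."""
    D = 2.0 * (fit_decj.lnL - fit_dec.lnL)
    if D < -1e-8:
        raise ValueError(f"DEC+j likelihood below DEC ({D=}): optimizer failure")
    D = max(D, 0.0)
    return LRTResult(D, 1, float(chi2.sf(D, 1)))
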