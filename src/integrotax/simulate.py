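"""Synthetic multi-modal datasets with known ground truth.

Every pipeline stage is testable without downloads: a pure-birth tree carries
a two-parameter (transition/transversion) substitution process so the K2P
metric is the correct estimator by construction; morphometric tables combine
population-specific allometric slopes on SL with lognormal noise, half-unit
meristic counts and missing-at-random cells; GPS points cluster around
per-basin centroids; and tip ranges evolve forward under DEC(+j) with known
(d, e, j) via Gillespie simulation along branches and the cladogenetic event
distribution at nodes.

One global seed fans out to independent per-stream child seeds (tree,
sequences, morphometrics, coordinates, ranges) so each stage can be
regenerated on its own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

from .biogeography import (DECParams, RangeStateSpace, build_rate_matrix,
                           clado_event_weights)
from .tables import (GeoPoints, MorphoTable, SequenceSet, TipRangeTable)

import pandas as pd

__all__ = ["SyntheticTruth", "simulate_tree", "simulate_sequences",
           "simulate_morpho", "simulate_coordinates", "simulate_ranges",
           "three_species_preset", "child_seeds"]


def child_seeds(seed: int, n: int = 5) -> list[int]:
    """Deterministic per-stream child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


@dataclass
class SyntheticTruth:
    """Serializable record of every generating parameter of a preset."""

    seed: int
    n_species: int
    n_per_species: int
    tree_newick: str
    birth_rate: float
    kappa: float
    seq_rate: float
    seq_length: int
    morpho_slopes: dict
    morpho_noise_sd: float
    meristic_means: dict
    missing_rate: float
    sl_range: tuple
    basin_centroids: dict
    coord_jitter_sd_deg: float
    dec_params: tuple
    areas: list
    max_range_size: int

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2, default=list)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  seed: int | None = None) -> dendropy.Tree:
    """Pure-birth (Yule) tree; branch lengths in expected-substitution units.

    Lineages split at rate ``birth_rate`` each; after the (n_tips)-th
    speciation, one further waiting time at the full rate extends every
    pendant branch, so no tip edge has length zero and the expected
    root-to-tip depth is ``(1/birth_rate) * sum_{k=2}^{n_tips} 1/k``.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    left, right = dendropy.Node(), dendropy.Node()
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    pendant = [left, right]
    for node in pendant:
        node.edge.length = 0.0
    while len(pendant) < n_tips:
        wait = rng.exponential(1.0 / (birth_rate * len(pendant)))
        for node in pendant:
            node.edge.length += wait
        k = int(rng.integers(len(pendant)))
        parent = pendant.pop(k)
        a, b = dendropy.Node(), dendropy.Node()
        a.edge.length = b.edge.length = 0.0
        parent.add_child(a)
        parent.add_child(b)
        pendant.extend([a, b])
    final_wait = rng.exponential(1.0 / (birth_rate * len(pendant)))
    for node in pendant:
        node.edge.length += final_wait
    ns = dendropy.TaxonNamespace()
    for i, node in enumerate(pendant):
        node.taxon = ns.new_taxon(label=f"t{i + 1}")
    tree.taxon_namespace = ns
    return tree


# ---------------------------------------------------------------------------
# sequences: two-parameter (K80) process
# ---------------------------------------------------------------------------

_NUC = np.array(list("AGCT"))


def _k80_generator(kappa: float) -> np.ndarray:
    """K80 rate matrix in A,G,C,T order, normalized to 1 expected
    substitution per unit branch length."""
    alpha = kappa      # transition rate (A<->G, C<->T)
    beta = 1.0         # transversion rate per partner
    Q = np.full((4, 4), beta)
    Q[0, 1] = Q[1, 0] = Q[2, 3] = Q[3, 2] = alpha
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = alpha + 2.0 * beta     # total leaving rate per nucleotide
    return Q / rate


def simulate_sequences(tree: dendropy.Tree, length: int = 600,
                       kappa: float = 4.0, rate: float = 1.0,
                       seed: int | None = None,
                       group_labels: dict | None = None) -> SequenceSet:
    """Evolve sites independently under the two-parameter substitution model.

    ``rate`` scales branch lengths into expected substitutions/site; with
    ``rate=0`` all sequences are identical to the root sequence.
    """
    rng = np.random.default_rng(seed)
    Q = _k80_generator(kappa)
    Pcache: dict[float, np.ndarray] = {}

    def trans(t: float) -> np.ndarray:
        P = Pcache.get(t)
        if P is None:
            P = expm(Q * (t * rate)) if t * rate > 0 else np.eye(4)
            P = np.clip(P, 0, None)
            P = P / P.sum(axis=1, keepdims=True)
            Pcache[t] = P
        return P

    root_seq = rng.integers(0, 4, size=length)
    states = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = states[id(node.parent_node)]
        P = trans(node.edge.length or 0.0)
        # vectorized per-site sampling from the parent-conditioned rows
        u = rng.random(length)
        cdf = np.cumsum(P, axis=1)
        states[id(node)] = (u[:, None] > cdf[parent]).sum(axis=1)
    ids, seqs, groups = [], [], []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        ids.append(label)
        seqs.append("".join(_NUC[states[id(leaf)]]))
        if group_labels is not None:
            groups.append(group_labels[label])
    return SequenceSet(ids, seqs, groups if group_labels is not None else None)


# ---------------------------------------------------------------------------
# morphometrics
# ---------------------------------------------------------------------------

def simulate_morpho(populations: list[str], n_per_pop: int,
                    slopes: dict, meristic_means: dict,
                    sl_range: tuple = (25.0, 120.0),
                    noise_sd: float = 0.05, missing_rate: float = 0.02,
                    juvenile_fraction: float = 0.0,
                    seed: int | None = None) -> MorphoTable:
    """Group-structured morphometric table with allometric scaling on SL.

    ``slopes[pop]`` maps each morphometric variable to its population slope:
    ``value = slope * SL * exp(noise)`` with lognormal noise of SD
    ``noise_sd`` on the log scale.  ``meristic_means[pop]`` maps meristic
    variables to means; counts are Gaussians rounded to the half-unit grid.
    A ``juvenile_fraction`` of specimens receives SL below 20 mm.  Missing
    cells (never in SL) are dropped at random at ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    morpho_vars = sorted(next(iter(slopes.values())))
    meristic_vars = sorted(next(iter(meristic_means.values())))
    rows, ids, groups = [], [], []
    for pop in populations:
        for k in range(n_per_pop):
            if rng.random() < juvenile_fraction:
                sl = rng.uniform(10.0, 19.5)
            else:
                sl = rng.uniform(*sl_range)
            row = {"SL": sl}
            for v in morpho_vars:
                row[v] = slopes[pop][v] * sl * np.exp(rng.normal(0, noise_sd))
            for v in meristic_vars:
                row[v] = np.round(rng.normal(meristic_means[pop][v], 0.5) * 2) / 2
            rows.append(row)
            ids.append(f"{pop}_{k + 1}")
            groups.append(pop)
    values = pd.DataFrame(rows, index=ids)
    # missing at random, never in SL
    maskable = [c for c in values.columns if c != "SL"]
    mask = rng.random(values[maskable].shape) < missing_rate
    values[maskable] = values[maskable].mask(mask)
    kinds = {"SL": "SL"}
    kinds.update({v: "morphometric_SL" for v in morpho_vars})
    kinds.update({v: "meristic" for v in meristic_vars})
    table = MorphoTable(values, pd.Series(groups, index=ids), kinds)
    table.meta["n_masked"] = int(mask.sum())
    return table


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def simulate_coordinates(ids: list[str], basin_of: dict,
                         centroids: dict, jitter_sd_deg: float = 0.05,
                         seed: int | None = None) -> GeoPoints:
    """Per-basin clustered GPS points: centroid + Gaussian jitter (degrees)."""
    rng = np.random.default_rng(seed)
    lat, lon = [], []
    for i in ids:
        c_lat, c_lon = centroids[basin_of[i]]
        lat.append(c_lat + rng.normal(0, jitter_sd_deg))
        lon.append(c_lon + rng.normal(0, jitter_sd_deg))
    return GeoPoints(list(ids), np.array(lat), np.array(lon))


# ---------------------------------------------------------------------------
# DEC forward simulation
# ---------------------------------------------------------------------------

def simulate_ranges(tree: dendropy.Tree, space: RangeStateSpace,
                    params: DECParams, seed: int | None = None,
                    root_range: frozenset | None = None) -> TipRangeTable:
    """Forward DEC(+j) simulation: Gillespie anagenesis along branches,
    cladogenetic sampling at nodes.

    Lineages whose range hits the null (extinct) state are re-drawn from the
    root (rejection) so every tip carries a nonempty observed range, matching
    the conditioning of the inference (tips always observed).
    """
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(space, params)
    nonnull = list(range(1, space.n_states))

    def evolve(state_idx: int, t: float) -> int:
        while t > 0:
            rate = -Q[state_idx, state_idx]
            if rate <= 0:
                return state_idx
            wait = rng.exponential(1.0 / rate)
            if wait > t:
                return state_idx
            t -= wait
            p = Q[state_idx].clip(0)
            p = p / p.sum()
            state_idx = rng.choice(space.n_states, p=p)
            if state_idx == 0:
                return 0
        return state_idx

    for _attempt in range(200):
        if root_range is not None:
            root_idx = space.index[frozenset(root_range)]
        else:
            root_idx = int(rng.choice(nonnull))
        state = {id(tree.seed_node): root_idx}
        extinct = False
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            anc_idx = state[id(node)]
            if anc_idx == 0:
                extinct = True
                break
            pairs = clado_event_weights(space.states[anc_idx], space, params)
            keys = list(pairs)
            probs = np.array([pairs[k] for k in keys])
            left_rng, right_rng = keys[rng.choice(len(keys), p=probs)]
            children = node.child_nodes()
            for child, crng in zip(children, (left_rng, right_rng)):
                s = evolve(space.index[crng], child.edge.length or 0.0)
                state[id(child)] = s
                if s == 0 and child.is_leaf():
                    extinct = True
            if extinct:
                break
        if extinct:
            continue
        if any(state[id(leaf)] == 0 for leaf in tree.leaf_node_iter()):
            continue
        ranges = {leaf.taxon.label: space.states[state[id(leaf)]]
                  for leaf in tree.leaf_node_iter()}
        return TipRangeTable(list(space.areas), ranges)
    raise RuntimeError("range simulation kept going extinct; "
                       "lower e or raise d")


# ---------------------------------------------------------------------------
# the three-species preset
# ---------------------------------------------------------------------------

def three_species_preset(seed: int = 7, n_per_species: int = 12,
                         seq_length: int = 600):
    """Coherent dataset of three well-separated species for end-to-end runs.

    Returns a dict with keys ``tree``, ``sequences``, ``morpho``, ``gps``,
    ``ranges``, ``space``, ``truth``.  Species differ in morphometric slopes
    (well beyond the within-population noise), occupy distinct river basins,
    and are deeply divergent on the tree, so the ground truth is three
    recoverable clusters.
    """
    s_tree, s_seq, s_morpho, s_geo, s_rng = child_seeds(seed, 5)
    species = ["spA", "spB", "spC"]
    n_tips = 3 * n_per_species

    # species tree: three deep clades built explicitly so separation is known
    rng = np.random.default_rng(s_tree)

    def clade(prefix: str, n: int) -> str:
        # ladder of short within-species branches
        tips = [f"{prefix}_{i + 1}:{rng.uniform(0.001, 0.01):.5f}" for i in range(n)]
        s = tips[0]
        for t in tips[1:]:
            s = f"({s},{t}):{rng.uniform(0.001, 0.01):.5f}"
        return s

    newick = (f"(({clade('spA', n_per_species)}:0.15,"
              f"{clade('spB', n_per_species)}:0.15):0.1,"
              f"{clade('spC', n_per_species)}:0.25);")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True

    species_of = {f"{sp}_{i + 1}": sp for sp in species
                  for i in range(n_per_species)}
    seqs = simulate_sequences(tree, length=seq_length, kappa=4.0, rate=1.0,
                              seed=s_seq, group_labels=species_of)

    morpho_vars = ["HL", "SnL", "OD", "CPL", "CPD", "PSL", "DSL", "IntD"]
    base = {"HL": 0.32, "SnL": 0.18, "OD": 0.05, "CPL": 0.16,
            "CPD": 0.09, "PSL": 0.28, "DSL": 0.26, "IntD": 0.20}
    shift = {"spA": 1.0, "spB": 1.25, "spC": 0.8}
    slopes = {sp: {v: base[v] * shift[sp] ** (1 if k % 2 == 0 else -1)
                   for k, v in enumerate(morpho_vars)} for sp in species}
    meristic_means = {"spA": {"plates": 24.0, "teeth": 40.0},
                      "spB": {"plates": 27.0, "teeth": 52.0},
                      "spC": {"plates": 21.5, "teeth": 33.0}}
    noise_sd, missing_rate = 0.04, 0.02
    morpho = simulate_morpho(species, n_per_species, slopes, meristic_means,
                             noise_sd=noise_sd, missing_rate=missing_rate,
                             seed=s_morpho)

    centroids = {"spA": (4.0, -54.5), "spB": (4.8, -53.2), "spC": (3.2, -52.3)}
    gps = simulate_coordinates(list(species_of), species_of, centroids,
                               jitter_sd_deg=0.05, seed=s_geo)

    areas = ["W", "C", "E", "S", "N"]
    space = RangeStateSpace(areas, max_range_size=3)
    dec_params = DECParams(d=0.3, e=0.05, j=0.0)
    ranges = simulate_ranges(tree, space, dec_params, seed=s_rng)

    truth = SyntheticTruth(
        seed=seed, n_species=3, n_per_species=n_per_species,
        tree_newick=newick, birth_rate=float("nan"), kappa=4.0, seq_rate=1.0,
        seq_length=seq_length, morpho_slopes=slopes, morpho_noise_sd=noise_sd,
        meristic_means=meristic_means, missing_rate=missing_rate,
        sl_range=(25.0, 120.0), basin_centroids=centroids,
        coord_jitter_sd_deg=0.05, dec_params=(0.3, 0.05, 0.0),
        areas=areas, max_range_size=3)
    return {"tree": tree, "sequences": seqs, "morpho": morpho, "gps": gps,
            "ranges": ranges, "space": space, "species_of": species_of,
            "truth": truth}
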