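"""Independent oracle implementations used by the acceptance checks.

These deliberately avoid the package's own code paths: the K2P oracle counts
per-site differences with plain Python, and the DEC oracle enumerates every
internal-node state assignment with explicit matrix exponentials.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm

from integrotax.biogeography import build_rate_matrix, clado_event_weights


def counting_k2p(a: str, b: str) -> float:
    purines = {"A", "G"}
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    if n == 0:
        return math.nan
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def plain_dec_pairs(space, anc):
    """Ordered daughter pairs of classic DEC (no jump category at all),
    uniformly weighted: sympatric copy for size-1 ranges; subset sympatry
    and single-area vicariance for larger ranges."""
    anc = frozenset(anc)
    if len(anc) == 1:
        return {(anc, anc): 1.0}
    pairs = set()
    for a in sorted(anc):
        single = frozenset({a})
        pairs.add((anc, single))
        pairs.add((single, anc))
        pairs.add((single, anc - single))
        pairs.add((anc - single, single))
    return {p: 1.0 / len(pairs) for p in pairs}


def brute_force_dec_loglik(tree, tip_ranges, space, params,
                           plain_dec: bool = False) -> float:
    """Sum over all internal-node state assignments and daughter pairs.

    With ``plain_dec=True`` the cladogenetic distribution comes from
    :func:`plain_dec_pairs` (no jump events enumerated), an independent
    route for checking that the founder-weight model at j = 0 collapses to
    classic DEC.
    """
    Q = build_rate_matrix(space, params)
    nodes = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    cache = {}

    def P(t):
        if t not in cache:
            cache[t] = expm(Q * t)
        return cache[t]

    total = 0.0
    for assign in itertools.product(range(1, space.n_states),
                                    repeat=len(nodes)):
        st = dict(zip([id(n) for n in nodes], assign))
        like = 1.0 / space.n_nonnull
        for n in nodes:
            anc = space.states[st[id(n)]]
            pairs = (plain_dec_pairs(space, anc) if plain_dec
                     else clado_event_weights(anc, space, params))
            ca, cb = n.child_nodes()

            def child_state(c):
                if c.is_leaf():
                    return space.index[tip_ranges.ranges[c.taxon.label]]
                return st[id(c)]

            s = 0.0
            for (l, r), p in pairs.items():
                s += (p * P(ca.edge.length)[space.index[l], child_state(ca)]
                      * P(cb.edge.length)[space.index[r], child_state(cb)])
            like *= s
        total += like
    return float(np.log(total))
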