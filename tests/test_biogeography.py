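import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from integrotax.biogeography import (CladoStructure, DECModel, DECParams,
                                     build_rate_matrix, build_state_space,
                                     clado_event_weights, fit_ml, likelihood,
                                     lrt)
from integrotax.tables import TipRangeTable, read_newick


def brute_force_likelihood(tree, tr, space, params):
    """Exhaustive summation over all internal-node state assignments and
    cladogenetic daughter pairs (independent of the pruning recursion)."""
    Q = build_rate_matrix(space, params)
    nodes = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    Pm = {}

    def P(t):
        if t not in Pm:
            Pm[t] = expm(Q * t)
        return Pm[t]

    total = 0.0
    for assign in itertools.product(range(1, space.n_states),
                                    repeat=len(nodes)):
        st = dict(zip([id(n) for n in nodes], assign))
        like = 1.0 / space.n_nonnull
        for n in nodes:
            i = st[id(n)]
            pairs = clado_event_weights(space.states[i], space, params)
            ca, cb = n.child_nodes()

            def child_state(c):
                if c.is_leaf():
                    return space.index[tr.ranges[c.taxon.label]]
                return st[id(c)]

            s = 0.0
            for (l, r), p in pairs.items():
                s += (p * P(ca.edge.length)[space.index[l], child_state(ca)]
                      * P(cb.edge.length)[space.index[r], child_state(cb)])
            like *= s
        total += like
    return np.log(total)


class TestStateSpace:
    def test_two_areas_max_two(self):
        sp = build_state_space(["A", "B"], 2)
        assert sp.n_nonnull == 3
        assert sp.states[0] == frozenset()

    def test_eleven_areas_max_four_enumeration_oracle(self):
        from math import comb
        sp = build_state_space([f"a{i}" for i in range(11)], 4)
        expected = sum(comb(11, k) for k in range(1, 5))
        assert sp.n_nonnull == expected == 561

    def test_three_areas_max_one(self):
        sp = build_state_space(["A", "B", "C"], 1)
        assert sp.n_nonnull == 3

    def test_invalid_max_rejected(self):
        with pytest.raises(ValueError):
            build_state_space(["A"], 0)


class TestRateMatrix:
    def test_zero_rates_zero_matrix(self):
        sp = build_state_space(["A", "B"], 2)
        Q = build_rate_matrix(sp, DECParams(0.0, 0.0))
        np.testing.assert_allclose(Q, 0.0)

    def test_two_area_rates_by_definition(self):
        sp = build_state_space(["A", "B"], 2)
        Q = build_rate_matrix(sp, DECParams(d=0.3, e=0.1))
        iA, iB = sp.index[frozenset("A")], sp.index[frozenset("B")]
        iAB = sp.index[frozenset("AB")]
        assert Q[iA, iAB] == pytest.approx(0.3)
        assert Q[iAB, iA] == pytest.approx(0.1)      # losing B
        assert Q[iA, 0] == pytest.approx(0.1)        # size-1 to null
        assert Q[0].sum() == 0.0                     # null absorbing

    def test_expansion_rate_scales_with_range_size(self):
        sp = build_state_space(["A", "B", "C"], 3)
        Q = build_rate_matrix(sp, DECParams(d=0.2, e=0.0))
        iAB = sp.index[frozenset("AB")]
        iABC = sp.index[frozenset("ABC")]
        assert Q[iAB, iABC] == pytest.approx(2 * 0.2)

    def test_row_sums_zero_and_expm_stochastic(self):
        sp = build_state_space(["A", "B", "C"], 2)
        Q = build_rate_matrix(sp, DECParams(0.7, 0.4))
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        for t in (0.1, 1.0, 10.0):
            np.testing.assert_allclose(expm(Q * t).sum(axis=1), 1.0, atol=1e-8)


class TestCladogenesis:
    def test_single_area_j_zero_sympatric_copy(self):
        sp = build_state_space(["A", "B"], 2)
        w = clado_event_weights(frozenset("A"), sp, DECParams(0.1, 0.1, 0.0))
        assert w[(frozenset("A"), frozenset("A"))] == pytest.approx(1.0)

    def test_j_zero_matches_plain_dec_enumeration(self):
        sp = build_state_space(["A", "B"], 2)
        w = clado_event_weights(frozenset("AB"), sp, DECParams(0.1, 0.1, 0.0))
        # subset sympatry (AB,A),(A,AB),(AB,B),(B,AB); vicariance (A,B),(B,A)
        assert len(w) == 6
        np.testing.assert_allclose(sorted(w.values()), [1 / 6] * 6)
        assert sum(w.values()) == pytest.approx(1.0)

    def test_jump_pairs_appear_with_positive_j(self):
        sp = build_state_space(["A", "B", "C"], 2)
        w0 = clado_event_weights(frozenset("A"), sp, DECParams(0.1, 0.1, 0.0))
        wj = clado_event_weights(frozenset("A"), sp, DECParams(0.1, 0.1, 1.0))
        jump_pair = (frozenset("A"), frozenset("B"))
        assert jump_pair not in w0 or w0[jump_pair] == 0.0
        assert wj[jump_pair] > 0
        assert sum(wj.values()) == pytest.approx(1.0)

    def test_empty_range_rejected(self):
        sp = build_state_space(["A"], 1)
        with pytest.raises(ValueError):
            clado_event_weights(frozenset(), sp, DECParams(0.1, 0.1))

    def test_structure_probabilities_match_dict_form(self):
        sp = build_state_space(["A", "B", "C"], 3)
        cs = CladoStructure(sp)
        for j in (0.0, 0.5, 2.0):
            prob = cs.probabilities(j)
            params = DECParams(0.1, 0.1, j)
            for i, rng in enumerate(sp.states):
                if not rng:
                    continue
                w = clado_event_weights(rng, sp, params)
                mask = cs.anc == i
                got = {}
                for l, r, p in zip(cs.left[mask], cs.right[mask], prob[mask]):
                    got[(sp.states[l], sp.states[r])] = \
                        got.get((sp.states[l], sp.states[r]), 0.0) + p
                for pair, p in w.items():
                    assert got[pair] == pytest.approx(p, rel=1e-12)


class TestLikelihood:
    def test_cherry_zero_rates_root_prior_only(self):
        sp = build_state_space(["A", "B"], 2)
        tree = read_newick("(t1:1.0,t2:1.0);")
        tr = TipRangeTable(["A", "B"], {"t1": {"A"}, "t2": {"A"}})
        ll = likelihood(tree, tr, sp, DECParams(1e-12, 1e-12, 0.0))
        assert ll == pytest.approx(np.log(1 / 3), abs=1e-6)

    def test_single_branch_decay_matrix_exponential_oracle(self):
        # {A} -> null at rate e=1: P(still {A} after t=1) = exp(-1)
        sp = build_state_space(["A"], 1)
        Q = build_rate_matrix(sp, DECParams(d=0.0, e=1.0))
        P = expm(Q * 1.0)
        assert P[1, 1] == pytest.approx(np.exp(-1), rel=1e-10)
        assert P[1, 1] == pytest.approx(0.3678794, abs=1e-7)

    def test_pruning_equals_brute_force_enumeration(self):
        sp = build_state_space(["A", "B", "C"], 3)
        tree = read_newick("((t1:0.7,t2:1.2):0.5,(t3:0.9,t4:0.3):1.1);")
        tr = TipRangeTable(["A", "B", "C"],
                           {"t1": {"A"}, "t2": {"A", "B"},
                            "t3": {"C"}, "t4": {"B", "C"}})
        for params in (DECParams(0.3, 0.1, 0.0), DECParams(0.5, 0.3, 0.7),
                       DECParams(0.05, 0.5, 0.0), DECParams(1.0, 0.01, 2.5)):
            bf = brute_force_likelihood(tree, tr, sp, params)
            pr = likelihood(tree, tr, sp, params)
            assert pr == pytest.approx(bf, abs=1e-8)

    def test_decj_with_j_zero_equals_dec(self):
        rng = np.random.default_rng(20)
        sp = build_state_space(["A", "B", "C"], 2)
        from integrotax.simulate import simulate_ranges, simulate_tree
        for k in range(20):
            tree = simulate_tree(6, birth_rate=1.0, seed=int(rng.integers(2**31)))
            tr = simulate_ranges(tree, sp, DECParams(0.4, 0.05),
                                 seed=int(rng.integers(2**31)))
            d, e = rng.uniform(0.05, 1.0, 2)
            l1 = likelihood(tree, tr, sp, DECParams(d, e, 0.0))
            l2 = likelihood(tree, tr, sp, DECParams(d, e, 1e-300))
            assert l1 == pytest.approx(l2, abs=1e-10)

    def test_invariant_to_child_order(self):
        sp = build_state_space(["A", "B"], 2)
        t1 = read_newick("((t1:0.5,t2:0.8):0.3,t3:1.0);")
        t2 = read_newick("(t3:1.0,(t2:0.8,t1:0.5):0.3);")
        tr = TipRangeTable(["A", "B"],
                           {"t1": {"A"}, "t2": {"B"}, "t3": {"A", "B"}})
        p = DECParams(0.4, 0.2, 0.3)
        assert likelihood(t1, tr, sp, p) == pytest.approx(
            likelihood(t2, tr, sp, p), rel=1e-12)

    def test_missing_tip_range_rejected(self):
        sp = build_state_space(["A"], 1)
        tree = read_newick("(t1:1.0,t2:1.0);")
        tr = TipRangeTable(["A"], {"t1": {"A"}})
        with pytest.raises(Exception, match="t2"):
            likelihood(tree, tr, sp, DECParams(0.1, 0.1))


class TestMarginals:
    def test_rows_sum_to_one(self):
        sp = build_state_space(["A", "B", "C"], 2)
        tree = read_newick("((t1:0.7,t2:1.2):0.5,(t3:0.9,t4:0.3):1.1);")
        tr = TipRangeTable(["A", "B", "C"],
                           {"t1": {"A"}, "t2": {"A"}, "t3": {"C"}, "t4": {"B"}})
        model = DECModel(tree, tr, sp, "DEC")
        marg = model.pruner.node_marginals(DECParams(0.3, 0.1))
        np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-10)
        assert marg.to_numpy().min() >= 0

    def test_low_rates_identical_tips_concentrate_on_shared_range(self):
        sp = build_state_space(["A", "B"], 2)
        tree = read_newick("((t1:0.5,t2:0.5):0.5,t3:1.0);")
        tr = TipRangeTable(["A", "B"], {"t1": {"B"}, "t2": {"B"}, "t3": {"B"}})
        model = DECModel(tree, tr, sp, "DEC")
        marg = model.pruner.node_marginals(DECParams(1e-6, 1e-6))
        assert (marg["B"] > 0.999).all()

    def test_marginal_matches_clamped_reroot_oracle(self):
        # marginal at a node == likelihood with that node clamped, normalized
        sp = build_state_space(["A", "B"], 2)
        tree = read_newick("((t1:0.7,t2:1.2):0.5,t3:0.9);")
        tr = TipRangeTable(["A", "B"], {"t1": {"A"}, "t2": {"B"}, "t3": {"A"}})
        params = DECParams(0.4, 0.15, 0.5)
        model = DECModel(tree, tr, sp, "DEC+J")
        marg = model.pruner.node_marginals(params)

        # clamped brute force at the root's first internal child
        Q = build_rate_matrix(sp, params)
        nodes = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        target = nodes[1]          # the (t1,t2) ancestor
        liks = []
        for istate in range(1, sp.n_states):
            total = 0.0
            for assign in itertools.product(range(1, sp.n_states),
                                            repeat=len(nodes)):
                st = dict(zip([id(n) for n in nodes], assign))
                if st[id(target)] != istate:
                    continue
                like = 1.0 / sp.n_nonnull
                for n in nodes:
                    pairs = clado_event_weights(sp.states[st[id(n)]], sp, params)
                    ca, cb = n.child_nodes()

                    def cs(c):
                        return (sp.index[tr.ranges[c.taxon.label]]
                                if c.is_leaf() else st[id(c)])

                    s = 0.0
                    for (l, r), p in pairs.items():
                        s += (p * expm(Q * ca.edge.length)[sp.index[l], cs(ca)]
                              * expm(Q * cb.edge.length)[sp.index[r], cs(cb)])
                    like *= s
                total += like
            liks.append(total)
        oracle = np.array(liks) / sum(liks)
        row = marg.iloc[1].to_numpy()[1:]      # drop null column
        np.testing.assert_allclose(row, oracle, atol=1e-8)


class TestFitAndLRT:
    def test_dec_forces_j_zero(self):
        sp = build_state_space(["A", "B"], 2)
        tree = read_newick("((t1:0.5,t2:0.8):0.3,(t3:0.6,t4:0.9):0.4);")
        tr = TipRangeTable(["A", "B"], {"t1": {"A"}, "t2": {"A"},
                                        "t3": {"B"}, "t4": {"B"}})
        fit = fit_ml(tree, tr, sp, model="DEC", n_starts=2, seed=0)
        assert fit.params.j == 0.0
        assert fit.n_params == 2
        fitj = fit_ml(tree, tr, sp, model="DEC+J", n_starts=2, seed=0)
        assert fitj.n_params == 3
        assert fitj.lnL >= fit.lnL - 1e-6     # nested models

    def test_lrt_equal_likelihoods(self):
        from integrotax.biogeography import DECResults
        a = DECResults("DEC", DECParams(0.1, 0.1), -50.0, 2, True)
        b = DECResults("DEC+J", DECParams(0.1, 0.1, 0.0), -50.0, 3, True)
        res = lrt(a, b)
        assert res.D == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_lrt_chi_squared_quantile_identity(self):
        from integrotax.biogeography import DECResults
        a = DECResults("DEC", DECParams(0.1, 0.1), -50.0, 2, True)
        b = DECResults("DEC+J", DECParams(0.1, 0.1, 0.5), -50.0 + 3.841 / 2,
                       3, True)
        res = lrt(a, b)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0500, abs=5e-4)
        assert res.p_value == pytest.approx(chi2.sf(3.841, 1), rel=1e-12)

    def test_lrt_rejects_negative_statistic(self):
        from integrotax.biogeography import DECResults
        a = DECResults("DEC", DECParams(0.1, 0.1), -50.0, 2, True)
        b = DECResults("DEC+J", DECParams(0.1, 0.1), -51.0, 3, True)
        with pytest.raises(ValueError):
            lrt(a, b)
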