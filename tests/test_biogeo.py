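"""DEC-family state space, rates, cladogenesis, likelihood and fitting."""

import itertools
import math

import numpy as np
import pytest

from phylocons import treeio
from phylocons.biogeo import (
    BiogeoFit,
    ancestral_ranges,
    anagenetic_q,
    build_state_space,
    cladogenesis_table,
    fit_model,
    range_likelihood,
    rank_models,
    read_geography,
    transition_probs,
    write_geography,
)

from _oracles import enumeration_likelihood_and_marginals, taylor_expm

FA, FB = frozenset("A"), frozenset("B")
FAB = frozenset("AB")


@pytest.fixture(scope="module")
def space2():
    return build_state_space(["A", "B"])


class TestStateSpace:
    def test_two_areas_full(self, space2):
        assert space2.states == (frozenset(), FA, FB, FAB)

    def test_three_areas_full(self):
        assert build_state_space(["A", "B", "C"]).n_states == 8

    def test_three_areas_max_one(self):
        space = build_state_space(["A", "B", "C"], max_range_size=1)
        assert space.n_states == 4
        assert all(len(s) <= 1 for s in space.states)

    def test_area_cap(self):
        with pytest.raises(ValueError, match="8"):
            build_state_space(list("ABCDEFGHI"))


class TestAnageneticQ:
    def test_single_area_rates(self, space2):
        Q = anagenetic_q(space2, d=0.3, e=0.1)
        i = space2.index[FA]
        assert Q[i, space2.index[FAB]] == pytest.approx(0.3)
        assert Q[i, space2.index[frozenset()]] == pytest.approx(0.1)
        assert Q[i, i] == pytest.approx(-0.4)

    def test_widespread_contraction(self, space2):
        Q = anagenetic_q(space2, d=0.3, e=0.1)
        i = space2.index[FAB]
        assert Q[i, space2.index[FA]] == pytest.approx(0.1)
        assert Q[i, space2.index[FB]] == pytest.approx(0.1)
        assert Q[i, i] == pytest.approx(-0.2)

    def test_expansion_scales_with_range_size(self):
        space = build_state_space(["A", "B", "C"])
        Q = anagenetic_q(space, d=0.2, e=0.0)
        assert Q[space.index[FAB], space.index[frozenset("ABC")]] == pytest.approx(0.4)

    def test_zero_rates_zero_matrix(self, space2):
        assert not anagenetic_q(space2, 0.0, 0.0).any()

    def test_rows_sum_to_zero(self):
        space = build_state_space(list("ABCD"), max_range_size=3)
        Q = anagenetic_q(space, 0.17, 0.05)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestTransitionProbs:
    def test_t_zero_identity(self, space2):
        Q = anagenetic_q(space2, 0.5, 0.2)
        assert np.allclose(transition_probs(Q, 0.0), np.eye(4))

    def test_zero_rates_identity(self, space2):
        Q = anagenetic_q(space2, 0.0, 0.0)
        assert np.allclose(transition_probs(Q, 3.7), np.eye(4))

    def test_matches_taylor_series_oracle(self, space2):
        rng = np.random.default_rng(42)
        for _ in range(5):
            d, e = rng.uniform(0.01, 1.0, size=2)
            Q = anagenetic_q(space2, d, e)
            assert np.allclose(
                transition_probs(Q, 0.7), taylor_expm(Q, 0.7), atol=1e-8
            )

    def test_rejects_non_generator(self):
        with pytest.raises(ValueError, match="generator"):
            transition_probs(np.array([[1.0, 0.0], [0.0, 1.0]]), 1.0)


class TestCladogenesis:
    def test_dec_single_area_sympatry(self, space2):
        table = cladogenesis_table(space2, "DEC")
        i = space2.index[FA]
        assert table.events[i] == [(i, i, 1.0)]

    def test_dec_widespread_six_events(self, space2):
        table = cladogenesis_table(space2, "DEC")
        events = table.events[space2.index[FAB]]
        assert len(events) == 6
        assert all(p == pytest.approx(1 / 6) for _, _, p in events)
        pairs = {(l, r) for l, r, _ in events}
        iA, iB, iAB = (space2.index[s] for s in (FA, FB, FAB))
        assert pairs == {(iA, iAB), (iAB, iA), (iB, iAB), (iAB, iB), (iA, iB), (iB, iA)}

    def test_divalike_excludes_subset_sympatry(self, space2):
        table = cladogenesis_table(space2, "DIVALIKE")
        events = table.events[space2.index[FAB]]
        iAB = space2.index[FAB]
        assert all(l != iAB and r != iAB for l, r, _ in events)
        assert len(events) == 2

    def test_bayarealike_exact_inheritance(self, space2):
        table = cladogenesis_table(space2, "BAYAREALIKE")
        i = space2.index[FAB]
        assert table.events[i] == [(i, i, 1.0)]

    def test_plus_j_zero_reduces_to_base(self, space2):
        base = cladogenesis_table(space2, "DEC", j=0.0)
        assert base.events == cladogenesis_table(space2, "DEC").events

    def test_jump_events_added(self, space2):
        table = cladogenesis_table(space2, "DEC", j=0.5)
        events = table.events[space2.index[FA]]
        # sympatry (w=1) + two ordered jumps to B (w=0.5 each)
        assert len(events) == 3
        probs = sorted(p for _, _, p in events)
        assert probs == pytest.approx([0.25, 0.25, 0.5])

    @pytest.mark.parametrize("model", ["DEC", "DIVALIKE", "BAYAREALIKE"])
    def test_rows_normalized_all_models_random_j(self, model):
        rng = np.random.default_rng(11)
        space = build_state_space(["A", "B", "C"])
        for j in (0.0, *rng.uniform(0.01, 3.0, size=3)):
            table = cladogenesis_table(space, model, j=float(j))
            for i, events in table.events.items():
                assert sum(p for _, _, p in events) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_model(self, space2):
        with pytest.raises(ValueError, match="unknown model"):
            cladogenesis_table(space2, "DIVA")


class TestRangeLikelihood:
    def test_zero_rate_limit(self, space2):
        tree = treeio.parse_newick("(A:1,B:1);")
        tips = {"A": FA, "B": FA}
        lnl = range_likelihood(tree, tips, space2, "DEC", 0.0, 0.0)
        assert lnl == pytest.approx(math.log(1 / 3))

    @pytest.mark.parametrize("model", ["DEC", "DIVALIKE", "BAYAREALIKE"])
    @pytest.mark.parametrize("shape", ["((A:1.3,B:0.8):0.9,C:2.1);", "(A:2.0,(B:0.6,C:1.1):0.8);"])
    def test_pruning_equals_enumeration(self, model, shape, space2):
        tree = treeio.parse_newick(shape)
        for coding in itertools.product([FA, FB, FAB], repeat=3):
            tips = dict(zip("ABC", coding))
            for d, e in [(0.05, 0.01), (0.3, 0.2)]:
                expected, _ = enumeration_likelihood_and_marginals(
                    tree, tips, space2, model, d, e
                )
                got = range_likelihood(tree, tips, space2, model, d, e)
                assert got == pytest.approx(expected, abs=1e-8)

    def test_plus_j_zero_matches_base(self, space2):
        tree = treeio.parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": FA, "B": FAB, "C": FB}
        base = range_likelihood(tree, tips, space2, "DEC", 0.1, 0.02)
        plus = range_likelihood(tree, tips, space2, "DEC", 0.1, 0.02, j=0.0)
        assert plus == pytest.approx(base, abs=1e-10)

    def test_child_order_invariance(self, space2):
        tree = treeio.parse_newick("((A:1.1,B:0.7):0.5,C:1.9);")
        swapped = treeio.parse_newick("(C:1.9,(B:0.7,A:1.1):0.5);")
        tips = {"A": FA, "B": FB, "C": FAB}
        assert range_likelihood(
            tree, tips, space2, "DEC", 0.2, 0.05, 0.3
        ) == pytest.approx(
            range_likelihood(swapped, tips, space2, "DEC", 0.2, 0.05, 0.3), abs=1e-10
        )

    def test_nonbinary_tree_rejected(self, space2):
        tree = treeio.parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(treeio.TreeError, match="binary"):
            range_likelihood(tree, {"A": FA, "B": FA, "C": FA}, space2, "DEC", 0.1, 0.1)

    def test_uncodable_tip_rejected(self):
        space = build_state_space(["A", "B"], max_range_size=1)
        tree = treeio.parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="state space"):
            range_likelihood(tree, {"A": FAB, "B": FA}, space, "DEC", 0.1, 0.1)


class TestFitAndRank:
    def test_degenerate_single_area_data_drives_d_to_bound(self, space2):
        tree = treeio.parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        tips = {t: FA for t in "ABCD"}
        fit = fit_model(tree, tips, space2, "DEC")
        assert fit.d <= 1e-6
        assert fit.converged

    def test_aicc_closed_form(self):
        fit = BiogeoFit("DEC", False, 0.1, 0.01, 0.0, lnL=-7.5, k=2, n_tips=7)
        assert fit.aicc == pytest.approx(-2 * -7.5 + 4 + 12 / 4)
        fitj = BiogeoFit("DEC", True, 0.1, 0.01, 0.1, lnL=-7.0, k=3, n_tips=7)
        assert fitj.aicc == pytest.approx(14 + 6 + 24 / 3)

    def test_rank_orders_by_aicc_then_k(self):
        fits = [
            BiogeoFit("DEC", True, 0.1, 0.0, 0.1, lnL=-8.0, k=3, n_tips=20, data_id="x"),
            BiogeoFit("DEC", False, 0.1, 0.0, 0.0, lnL=-9.231, k=2, n_tips=20, data_id="x"),
        ]
        # arrange an exact AICc tie: fit k=2 lnL so AICc matches the k=3 fit
        tie_lnl = -(fits[0].aicc - 4 - 12 / 17) / 2
        fits[1].lnL = tie_lnl
        table = rank_models(fits)
        assert table.iloc[0]["k"] == 2
        assert table["delta_AICc"].iloc[0] == 0.0

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="two"):
            rank_models([BiogeoFit("DEC", False, 0.1, 0.0, 0.0, -1.0, 2, 5)])

    def test_mixed_datasets_rejected(self):
        fits = [
            BiogeoFit("DEC", False, 0.1, 0.0, 0.0, -1.0, 2, 5, data_id="a"),
            BiogeoFit("DIVALIKE", False, 0.1, 0.0, 0.0, -1.0, 2, 5, data_id="b"),
        ]
        with pytest.raises(ValueError, match="different"):
            rank_models(fits)


class TestAncestralRanges:
    def test_zero_rate_limit_pins_root(self, space2):
        tree = treeio.parse_newick("((A:1,B:1):1,C:2);")
        tips = {"A": FB, "B": FB, "C": FB}
        marg = ancestral_ranges(tree, tips, space2, "DEC", 1e-9, 1e-12)
        root = marg[frozenset("ABC")]
        assert root["B"] == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_tips_symmetric_root(self, space2):
        tree = treeio.parse_newick("(A:1.4,B:1.4);")
        marg = ancestral_ranges(tree, {"A": FA, "B": FB}, space2, "DEC", 0.1, 0.02)
        root = marg[frozenset("AB")]
        assert root["A"] == pytest.approx(root["B"], rel=1e-9)

    @pytest.mark.parametrize("model", ["DEC", "DIVALIKE", "BAYAREALIKE"])
    def test_marginals_match_enumeration(self, model, space2):
        tree = treeio.parse_newick("((A:1.3,B:0.8):0.9,C:2.1);")
        tips = {"A": FAB, "B": FB, "C": FA}
        for j in (0.0, 0.7):
            _, oracle = enumeration_likelihood_and_marginals(
                tree, tips, space2, model, 0.13, 0.05, j
            )
            marg = ancestral_ranges(tree, tips, space2, model, 0.13, 0.05, j)
            for clade, probs in marg.items():
                for label, value in probs.items():
                    idx = space2.index[frozenset(label.split("+"))]
                    assert value == pytest.approx(oracle[clade][idx], abs=1e-8)

    def test_vectors_normalized(self, space2):
        tree = treeio.parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        tips = {"A": FA, "B": FAB, "C": FB, "D": FB}
        for probs in ancestral_ranges(tree, tips, space2, "DEC", 0.2, 0.05).values():
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)


class TestGeographyFiles:
    def test_round_trip(self, space2):
        coding = {"sp1": FA, "sp2": FAB, "sp3": FB}
        text = write_geography(space2, coding)
        space_back, coding_back = read_geography(text)
        assert space_back.areas == ("A", "B")
        assert coding_back == coding

    def test_null_coding_rejected(self):
        with pytest.raises(ValueError, match="null"):
            read_geography("1\t2\t(A B)\nsp1\t00\n")

    def test_bad_presence_string(self):
        with pytest.raises(ValueError, match="sp1"):
            read_geography("1\t2\t(A B)\nsp1\t1x\n")
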