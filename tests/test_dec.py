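import numpy as np
import pytest
from scipy.linalg import expm

from _oracles import brute_force_dec
from rangeflow import dec, simulate
from rangeflow.trees import parse_newick


def random_tips(tree, space, rng):
    nonnull = [s for s in space.states if s]
    return {l.taxon.label: nonnull[rng.integers(len(nonnull))]
            for l in tree.leaf_node_iter()}


class TestStateSpace:
    @pytest.mark.parametrize("areas, cap, observed, expected", [
        ("AB", 2, (), 4),          # full powerset incl. null
        ("ABCDEFGH", 3, (), 93),   # 1 + 8 + 28 + 56
        ("ABCDEFGH", 3, (0b1111,), 94),
    ])
    def test_state_counts(self, areas, cap, observed, expected):
        space = dec.build_state_space(tuple(areas), cap, observed)
        assert len(space) == expected
        assert space.states[0] == 0

    def test_canonical_order_and_uniqueness(self, eight_area_space):
        sizes = eight_area_space.sizes
        assert (np.diff(sizes) >= 0).all()
        assert len(set(eight_area_space.states)) == len(eight_area_space)

    def test_observed_range_outside_codebook_rejected(self):
        with pytest.raises(ValueError, match="codebook"):
            dec.build_state_space(tuple("AB"), 2, observed_ranges=(0b100,))


class TestQMatrix:
    def test_zero_rates_zero_matrix(self, two_area_space):
        Q = dec.build_q_matrix(two_area_space, dec.DECParams(0.0, 0.0))
        assert np.all(Q == 0)

    def test_single_step_rates(self, two_area_space):
        sp = two_area_space
        Q = dec.build_q_matrix(sp, dec.DECParams(0.3, 0.1))
        assert Q[sp.index[0b01], sp.index[0b11]] == pytest.approx(0.3)
        assert Q[sp.index[0b11], sp.index[0b01]] == pytest.approx(0.1)
        assert Q[sp.index[0b01], sp.index[0b00]] == pytest.approx(0.1)
        # gain rate scales with occupied-area count (one source per area)
        sp3 = dec.build_state_space(tuple("ABC"), 3)
        Q3 = dec.build_q_matrix(sp3, dec.DECParams(0.3, 0.1))
        assert Q3[sp3.index[0b011], sp3.index[0b111]] == pytest.approx(0.6)

    def test_rows_sum_to_zero_and_null_absorbing(self, eight_area_space):
        Q = dec.build_q_matrix(eight_area_space, dec.DECParams(0.7, 0.2))
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)
        assert np.all(Q[0] == 0)

    @pytest.mark.parametrize("t", [0.0, 0.5, 7.0, 100.0])
    def test_transition_probs_are_stochastic(self, eight_area_space, t):
        Q = dec.build_q_matrix(eight_area_space, dec.DECParams(0.05, 0.02))
        P = dec.branch_transition_probs(Q, t)
        np.testing.assert_allclose(P.sum(axis=1), 1, atol=1e-10)
        assert P.min() >= 0 and P.max() <= 1 + 1e-12

    def test_one_area_survival_closed_form(self):
        space = dec.build_state_space(tuple("A"), 1)
        Q = dec.build_q_matrix(space, dec.DECParams(0.0, 0.25))
        P = dec.branch_transition_probs(Q, 3.0)
        i = space.index[0b1]
        assert P[i, i] == pytest.approx(np.exp(-0.25 * 3.0), rel=1e-10)

    def test_semigroup_property(self, eight_area_space):
        Q = dec.build_q_matrix(eight_area_space, dec.DECParams(0.13, 0.07))
        P1 = dec.branch_transition_probs(Q, 1.0)
        P2 = dec.branch_transition_probs(Q, 2.0)
        np.testing.assert_allclose(P2, P1 @ P1, atol=1e-10)

    def test_negative_duration_rejected(self, two_area_space):
        Q = dec.build_q_matrix(two_area_space, dec.DECParams(0.1, 0.1))
        with pytest.raises(ValueError):
            dec.branch_transition_probs(Q, -1.0)


class TestCladogenesis:
    def test_single_area_duplicates(self):
        assert dec.enumerate_cladogenetic_outcomes(0b1) == [((1, 1), 1.0)]

    def test_two_area_outcomes(self):
        out = dec.enumerate_cladogenetic_outcomes(0b11)
        assert len(out) == 6
        pairs = {p for p, _ in out}
        assert pairs == {(1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2)}
        assert all(w == pytest.approx(1 / 6) for _, w in out)

    def test_three_area_outcome_count(self):
        out = dec.enumerate_cladogenetic_outcomes(0b111)
        assert len(out) == 12
        # vicariance splits are single area vs two-area remainder only
        for (l, r), _ in out:
            assert 1 in (bin(l).count("1"), bin(r).count("1"))

    @pytest.mark.parametrize("mask", list(range(1, 2 ** 4)))
    def test_weights_sum_to_one(self, mask):
        out = dec.enumerate_cladogenetic_outcomes(mask)
        assert sum(w for _, w in out) == pytest.approx(1.0)

    def test_null_range_rejected(self):
        with pytest.raises(ValueError):
            dec.enumerate_cladogenetic_outcomes(0)


class TestLikelihood:
    def test_two_tip_hand_pruning(self, two_area_space):
        """d=e=0, both tips {A}: only root {A} survives under the flat
        prior over the 3 non-null states."""
        tree = parse_newick("(t1:1.0,t2:1.0):0.0;", mode="chronogram")
        ll = dec.dec_loglik(tree, {"t1": 0b1, "t2": 0b1},
                            dec.DECParams(0.0, 0.0), two_area_space)
        assert ll == pytest.approx(np.log(1 / 3), rel=1e-12)

    def test_matches_exhaustive_enumeration(self, small_oracle_trees):
        rng = np.random.default_rng(7)
        for tree in small_oracle_trees:
            for n_areas in (2, 3):
                space = dec.build_state_space(tuple("ABC")[:n_areas], n_areas)
                tips = random_tips(tree, space, rng)
                params = dec.DECParams(rng.uniform(0.05, 1.0),
                                       rng.uniform(0.05, 1.0))
                expected, _ = brute_force_dec(tree, tips, params, space)
                got = dec.dec_loglik(tree, tips, params, space)
                assert got == pytest.approx(expected, rel=1e-8)

    def test_area_relabeling_invariance(self, small_oracle_trees):
        tree = small_oracle_trees[2]
        space = dec.build_state_space(tuple("ABC"), 2)
        params = dec.DECParams(0.2, 0.1)
        tips = {"t1": 0b001, "t2": 0b011, "t3": 0b100, "t4": 0b010}
        # swap areas A<->C consistently (bit 0 <-> bit 2)
        def swap(m):
            return ((m & 0b001) << 2) | (m & 0b010) | ((m & 0b100) >> 2)
        tips_swapped = {k: swap(v) for k, v in tips.items()}
        ll1 = dec.dec_loglik(tree, tips, params, space)
        ll2 = dec.dec_loglik(tree, tips_swapped, params, space)
        assert ll1 == pytest.approx(ll2, rel=1e-10)

    def test_null_state_inert_when_no_local_extinction(self,
                                                       small_oracle_trees):
        """With e=0 the absorbing null range is unreachable, so removing it
        from the state space leaves the likelihood unchanged."""
        tree = small_oracle_trees[2]
        space = dec.build_state_space(tuple("AB"), 2)
        no_null = dec.RangeStateSpace(tuple("AB"), 2,
                                      [s for s in space.states if s])
        params = dec.DECParams(0.4, 0.0)
        tips = {"t1": 0b01, "t2": 0b10, "t3": 0b11, "t4": 0b01}
        ll = dec.dec_loglik(tree, tips, params, space)
        ll_no_null = dec.dec_loglik(tree, tips, params, no_null)
        assert ll == pytest.approx(ll_no_null, rel=1e-12)

    def test_polytomy_rejected(self):
        tree = parse_newick("(t1:1.0,t2:1.0,t3:1.0):0.0;", mode="chronogram")
        space = dec.build_state_space(tuple("AB"), 2)
        with pytest.raises(Exception, match="binary"):
            dec.dec_loglik(tree, {"t1": 1, "t2": 1, "t3": 1},
                           dec.DECParams(0.1, 0.1), space)

    def test_impossible_data_gives_minus_inf(self):
        """Disjoint single-area tips with no dispersal and no widespread
        state available cannot be generated: all-zero root partial."""
        space = dec.build_state_space(tuple("AB"), 1)
        tree = parse_newick("(t1:1.0,t2:1.0):0.0;", mode="chronogram")
        with pytest.warns(RuntimeWarning, match="impossible"):
            ll = dec.dec_loglik(tree, {"t1": 0b01, "t2": 0b10},
                                dec.DECParams(0.0, 0.0), space)
        assert ll == -np.inf


class TestMarginals:
    def test_two_tip_certain_root(self, two_area_space):
        tree = parse_newick("(t1:1.0,t2:1.0):0.0;", mode="chronogram")
        out = dec.ancestral_range_marginals(
            tree, {"t1": 0b1, "t2": 0b1}, dec.DECParams(0.0, 0.0),
            two_area_space)
        assert len(out) == 1
        assert out.iloc[0]["range"] == "A"
        assert out.iloc[0]["probability"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, small_oracle_trees):
        rng = np.random.default_rng(13)
        for tree in small_oracle_trees[2:]:
            space = dec.build_state_space(tuple("ABC"), 3)
            tips = random_tips(tree, space, rng)
            params = dec.DECParams(0.3, 0.15)
            _, oracle = brute_force_dec(tree, tips, params, space)
            table = dec.ancestral_range_marginals(tree, tips, params, space)
            for _nid, grp in table.groupby("node_id"):
                key = frozenset(grp["clade"].iloc[0].split(","))
                ref = oracle[key]
                for _, row in grp.iterrows():
                    mask = dec.str_to_range(row["range"], space.areas)
                    assert row["probability"] == pytest.approx(
                        ref.get(mask, 0.0), abs=1e-8)

    def test_probabilities_sum_to_one(self, four_tip_chronogram):
        space = dec.build_state_space(tuple("ABCD"), 3)
        tips = {"t1": 0b0001, "t2": 0b0011, "t3": 0b0100, "t4": 0b1000}
        table = dec.ancestral_range_marginals(
            four_tip_chronogram, tips, dec.DECParams(0.2, 0.05), space)
        sums = table.groupby("node_id")["probability"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)

    def test_high_dispersal_flattens_root_toward_prior(self,
                                                       four_tip_chronogram):
        """As d grows with e=0 the root marginal approaches the flat prior
        (KL divergence decreases monotonically)."""
        space = dec.build_state_space(tuple("AB"), 2)
        tips = {"t1": 0b01, "t2": 0b10, "t3": 0b11, "t4": 0b01}
        kls = []
        for d in (0.05, 0.2, 1.0, 5.0, 10.0):
            table = dec.ancestral_range_marginals(
                four_tip_chronogram, tips, dec.DECParams(d, 0.0), space)
            root_id = table["node_id"].max()
            grp = table[table["node_id"] == root_id]
            p = np.zeros(len(space.node_state_idx))
            labels = [space.labels()[i] for i in space.node_state_idx]
            for _, row in grp.iterrows():
                p[labels.index(row["range"])] = row["probability"]
            q = np.full_like(p, 1.0 / len(p))
            mask = p > 0
            kls.append(float(np.sum(p[mask] * np.log(p[mask] / q[mask]))))
        assert all(b < a for a, b in zip(kls, kls[1:]))


class TestFit:
    def test_optimum_at_least_truth(self):
        rng = np.random.default_rng(3)
        space = dec.build_state_space(tuple("ABCD"), 2)
        tree = simulate.simulate_bd_tree(birth=0.12, death=0.0,
                                         n_tips=60, seed=3)
        truth = dec.DECParams(0.02, 0.01)
        tips, _, _ = simulate.simulate_dec_history(tree, truth, space, seed=3)
        params, ll, report = dec.fit_dec_ml(tree, tips, space)
        assert ll >= dec.dec_loglik(tree, tips, truth, space) - 1e-6
        assert report["converged"]

    def test_uniform_single_area_tips_drive_e_to_zero(self):
        """Identical one-area tips make any local extinction purely
        penalizing, so the profile in e is monotone toward the bound."""
        space = dec.build_state_space(tuple("AB"), 2)
        tree = simulate.simulate_bd_tree(birth=0.3, death=0.0,
                                         n_tips=12, seed=9)
        tips = {lab: 0b1 for lab in
                (l.taxon.label for l in tree.leaf_node_iter())}
        lls = [dec.dec_loglik(tree, tips, dec.DECParams(0.01, e), space)
               for e in (0.0, 0.01, 0.05, 0.2)]
        assert all(b < a for a, b in zip(lls, lls[1:]))
        params, _, _ = dec.fit_dec_ml(tree, tips, space)
        assert params.e < 1e-4


class TestRangeTableIO:
    def test_round_trip(self, tmp_path):
        areas = tuple("ABCD")
        tips = {"sp one": 0b0011, "sp_two": 0b1000, "sp3": 0b0100}
        path = tmp_path / "ranges.tsv"
        dec.write_range_table(tips, path, areas)
        again = dec.read_range_table(path, areas)
        assert again == tips

    def test_missing_area_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("species\tA\tB\nx\t1\t0\n")
        with pytest.raises(ValueError, match="lacks area columns"):
            dec.read_range_table(path, tuple("ABC"))
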