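import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugrepo.layers import (
    LayerError,
    binary_set_similarities,
    chem_dissimilarity,
    chem_dissimilarity_matrix,
    ppi_target_distance,
    signed_rank_profile,
    target_dissimilarity_matrix,
    target_overlap_dissimilarity,
    wsf_dissimilarity_matrix,
    wsf_raw,
)
from drugrepo.matrix import range_normalize


def brute_force_similarities(a: set, b: set):
    """Independent evaluation straight from the set-cardinality formulas."""
    inter = len(a & b)
    return (
        inter / len(a | b),
        inter / math.sqrt(len(a) * len(b)) if a and b else 0.0,
        2 * inter / (len(a) + len(b)),
    )


def bfs_distances(net: nx.Graph, sources):
    """Plain breadth-first search, independent of the implementation path."""
    dist = {s: 0 for s in sources if s in net}
    queue = list(dist)
    while queue:
        node = queue.pop(0)
        for nbr in net.neighbors(node):
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                queue.append(nbr)
    return dist


class TestSetSimilarities:
    def test_exhaustive_small_sets_match_oracle(self):
        universe = list(range(4))
        subsets = [
            set(c)
            for r in range(5)
            for c in itertools.combinations(universe, r)
        ]
        for a, b in itertools.product(subsets, repeat=2):
            if not a and not b:
                continue
            got = binary_set_similarities(frozenset(a), frozenset(b))
            np.testing.assert_allclose(got, brute_force_similarities(a, b), atol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.sets(st.integers(0, 9), max_size=10),
        st.sets(st.integers(0, 9), max_size=10),
    )
    def test_random_sets_match_oracle(self, a, b):
        if not a and not b:
            with pytest.raises(LayerError):
                binary_set_similarities(frozenset(a), frozenset(b))
            return
        got = binary_set_similarities(frozenset(a), frozenset(b))
        np.testing.assert_allclose(got, brute_force_similarities(a, b), atol=1e-12)
        assert all(0.0 <= v <= 1.0 for v in got)

    def test_bit_vector_and_set_inputs_agree(self):
        a, b = np.array([1, 0, 1, 1], dtype=np.uint8), np.array([0, 1, 1, 0], dtype=np.uint8)
        assert binary_set_similarities(a, b) == binary_set_similarities({0, 2, 3}, {1, 2})

    def test_length_mismatch_rejected(self):
        with pytest.raises(LayerError, match="length"):
            binary_set_similarities(np.array([1, 0]), np.array([1, 0, 1]))


class TestChemDissimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({1, 2}, {1, 2}, 0.0),
            ({1, 2}, {3, 4}, 1.0),
            ({1, 2}, {2, 3}, 1.0 - (1 / 3 + 1 / 2 + 1 / 2) / 3),  # = 5/9
        ],
    )
    def test_reference_values(self, a, b, expected):
        assert chem_dissimilarity(frozenset(a), frozenset(b)) == pytest.approx(expected)

    def test_decreasing_in_overlap_at_fixed_sizes(self):
        # |a| = |b| = 3; overlap 3, 2, 1, 0
        values = [
            chem_dissimilarity(frozenset({1, 2, 3}), frozenset(b))
            for b in ({1, 2, 3}, {1, 2, 4}, {1, 4, 5}, {4, 5, 6})
        ]
        assert values == sorted(values) and len(set(values)) == 4

    def test_matrix_agrees_with_scalar_route(self):
        rng = np.random.default_rng(5)
        fps = {f"d{i}": (rng.random(32) < 0.3).astype(np.uint8) for i in range(8)}
        for fp in fps.values():
            fp[0] = 1  # avoid empty fingerprints
        drugs = sorted(fps)
        matrix = chem_dissimilarity_matrix(fps, drugs)
        for i, a in enumerate(drugs):
            for j, b in enumerate(drugs):
                if i != j:
                    assert matrix.values[i, j] == pytest.approx(
                        chem_dissimilarity(fps[a], fps[b]), abs=1e-12
                    )

    def test_empty_fingerprint_rejected_at_matrix_construction(self):
        fps = {"d1": np.zeros(8, dtype=np.uint8), "d2": np.ones(8, dtype=np.uint8)}
        with pytest.raises(LayerError, match="d1"):
            chem_dissimilarity_matrix(fps, ["d1", "d2"])


class TestTargetLayer:
    def test_overlap_uses_chem_formula(self):
        assert target_overlap_dissimilarity({"p1", "p2"}, {"p2", "p3"}) == pytest.approx(5 / 9)
        assert target_overlap_dissimilarity({"p1"}, {"p1"}) == 0.0
        assert target_overlap_dissimilarity({"p1"}, {"p2"}) == 1.0
        with pytest.raises(LayerError):
            target_overlap_dissimilarity(set(), {"p1"})

    def test_shared_target_distance_zero(self):
        net = nx.path_graph(["p1", "p2", "p3"])
        assert ppi_target_distance({"p1"}, {"p1", "p3"}, net) == 0.0

    def test_path_distance(self):
        net = nx.path_graph(["p1", "p2", "p3"])
        assert ppi_target_distance({"p1"}, {"p3"}, net) == 2.0

    def test_disconnected_pair_returns_sentinel(self):
        net = nx.Graph([("p1", "p2")])
        net.add_edge("p8", "p9")
        assert ppi_target_distance({"p1"}, {"p9"}, net) is None

    def test_distance_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        cases = 0
        while cases < 1000:
            n = int(rng.integers(2, 13))
            net = nx.fast_gnp_random_graph(n, rng.uniform(0.1, 0.6),
                                           seed=int(rng.integers(2**31)))
            nodes = list(net.nodes)
            ti = set(rng.choice(nodes, size=int(rng.integers(1, n + 1)), replace=False).tolist())
            tj = set(rng.choice(nodes, size=int(rng.integers(1, n + 1)), replace=False).tolist())
            got = ppi_target_distance(ti, tj, net)
            if ti & tj:
                expected = 0.0
            else:
                dist = bfs_distances(net, ti)
                finite = [dist[t] for t in tj if t in dist]
                expected = float(min(finite)) if finite else None
            assert got == expected
            cases += 1

    def test_range_normalized_path_component(self):
        # raw min-path distances over the three pairs are {1, 3, 2}
        net = nx.path_graph(["p1", "p2", "p3", "p4"])
        targets = {"dA": frozenset({"p1"}), "dB": frozenset({"p2"}), "dC": frozenset({"p4"})}
        matrix = target_dissimilarity_matrix(targets, net, ["dA", "dB", "dC"])
        # overlap component is 1 for all (disjoint sets); path component is
        # the range-normalized {1,3,2} -> {0,1,0.5}
        assert matrix.loc("dA", "dB") == pytest.approx((1 + 0.0) / 2)
        assert matrix.loc("dA", "dC") == pytest.approx((1 + 1.0) / 2)
        assert matrix.loc("dB", "dC") == pytest.approx((1 + 0.5) / 2)

    def test_identical_target_sets_give_zero(self):
        net = nx.path_graph(["p1", "p2", "p3"])
        targets = {"dA": frozenset({"p1", "p2"}), "dB": frozenset({"p1", "p2"}),
                   "dC": frozenset({"p3"})}
        matrix = target_dissimilarity_matrix(targets, net, ["dA", "dB", "dC"])
        assert matrix.loc("dA", "dB") == 0.0

    def test_two_drug_degenerate_range_gives_half(self):
        # single off-diagonal pair: path range degenerate -> 0, overlap 1
        net = nx.Graph([("p1", "p2")])
        targets = {"dA": frozenset({"p1"}), "dB": frozenset({"p2"})}
        matrix = target_dissimilarity_matrix(targets, net, ["dA", "dB"])
        assert matrix.loc("dA", "dB") == pytest.approx(0.5)

    def test_unreachable_pairs_get_max_plus_one_before_normalization(self):
        net = nx.path_graph(["p1", "p2", "p3"])
        net.add_edge("q1", "q2")
        targets = {
            "dA": frozenset({"p1"}),
            "dB": frozenset({"p3"}),   # raw 2 from dA
            "dC": frozenset({"q1"}),   # unreachable from both -> raw 3
        }
        matrix = target_dissimilarity_matrix(targets, net, ["dA", "dB", "dC"])
        # path components: raw {AB:2, AC:3, BC:3} -> normalized {0, 1, 1}
        assert matrix.loc("dA", "dB") == pytest.approx((1 + 0.0) / 2)
        assert matrix.loc("dA", "dC") == pytest.approx((1 + 1.0) / 2)


class TestSignedRankProfile:
    def test_over_expressed_significant_genes_rank_first(self):
        stats = {"gA": (0.001, 1), "gB": (0.9, 1), "gC": (0.001, -1)}
        profile = signed_rank_profile(stats)
        ranks = dict(zip(profile.genes, profile.ranks))
        assert ranks == {"gA": 1.0, "gB": 2.0, "gC": 3.0}

    def test_literal_key_inverts_within_sign_ordering(self):
        stats = {"gA": (0.001, 1), "gB": (0.9, 1), "gC": (0.001, -1)}
        profile = signed_rank_profile(stats, rank_key="literal")
        ranks = dict(zip(profile.genes, profile.ranks))
        assert ranks["gB"] == 1.0  # high-p over-expressed first: the defect

    def test_total_tie_gives_midrank(self):
        stats = {f"g{i}": (1.0, 1) for i in range(5)}
        profile = signed_rank_profile(stats)
        assert np.all(profile.ranks == 3.0)
        assert np.all(profile.weights == 0.0)

    def test_single_gene(self):
        profile = signed_rank_profile({"g1": (0.25, -1)})
        assert profile.ranks.tolist() == [1.0]
        assert profile.weights.tolist() == [0.75]

    def test_sign_reversal_reverses_rank_order(self):
        rng = np.random.default_rng(2)
        p = np.round(1.0 - rng.random(30), 6)  # rounded to make exact ties unlikely
        signs = rng.choice([-1, 1], size=30)
        stats = {f"g{i:02d}": (float(p[i]), int(signs[i])) for i in range(30)}
        flipped = {g: (pv, -s) for g, (pv, s) in stats.items()}
        fwd = signed_rank_profile(stats)
        rev = signed_rank_profile(flipped)
        np.testing.assert_allclose(fwd.ranks + rev.ranks, 31.0)


class TestWSF:
    def make_profile(self, rng, genes):
        stats = {g: (float(1.0 - rng.random()), int(rng.choice([-1, 1]))) for g in genes}
        return signed_rank_profile(stats)

    def test_identical_profiles_give_zero(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        a = self.make_profile(rng, genes)
        assert wsf_raw(a, a) == 0.0

    def test_two_gene_reference_value(self):
        from drugrepo.layers import RankedProfile

        a = RankedProfile(("g1", "g2"), np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        b = RankedProfile(("g1", "g2"), np.array([2.0, 1.0]), np.array([0.5, 0.5]))
        assert wsf_raw(a, b) == pytest.approx(1.0)

    def test_raw_value_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:02d}" for i in range(20)]
        for _ in range(25):
            a, b = self.make_profile(rng, genes), self.make_profile(rng, genes)
            expected = sum(
                abs(a.ranks[k] - b.ranks[k]) * (a.weights[k] + b.weights[k]) / 2.0
                for k in range(20)
            )
            assert wsf_raw(a, b) == pytest.approx(expected, abs=1e-10)
            assert wsf_raw(b, a) == pytest.approx(wsf_raw(a, b), abs=1e-12)

    def test_invariant_to_gene_relabelling(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i:02d}" for i in range(15)]
        stats_a = {g: (float(1.0 - rng.random()), int(rng.choice([-1, 1]))) for g in genes}
        stats_b = {g: (float(1.0 - rng.random()), int(rng.choice([-1, 1]))) for g in genes}
        relabel = {g: f"h{i:02d}" for i, g in enumerate(reversed(genes))}
        a1, b1 = signed_rank_profile(stats_a), signed_rank_profile(stats_b)
        a2 = signed_rank_profile({relabel[g]: v for g, v in stats_a.items()})
        b2 = signed_rank_profile({relabel[g]: v for g, v in stats_b.items()})
        assert wsf_raw(a1, b1) == pytest.approx(wsf_raw(a2, b2), abs=1e-10)

    def test_matrix_is_range_normalized(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i:02d}" for i in range(20)]
        profiles = {f"d{i}": self.make_profile(rng, genes) for i in range(6)}
        matrix = wsf_dissimilarity_matrix(profiles, sorted(profiles))
        off = matrix.values[~np.eye(6, dtype=bool)]
        assert off.min() == 0.0 and off.max() == 1.0


def test_range_normalize_reference_case():
    raw = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0], [1.0, 2.0, 0.0]])
    out = range_normalize(raw)
    assert out[0, 1] == 0.0 and out[0, 2] == 0.5 and out[1, 2] == 1.0


def test_range_normalize_degenerate_range_gives_zeros():
    raw = np.full((3, 3), 4.0)
    np.fill_diagonal(raw, 0.0)
    assert np.all(range_normalize(raw) == 0.0)
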