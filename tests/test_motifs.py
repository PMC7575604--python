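"""Triad classification, census, randomization and significance profiles."""

from itertools import permutations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnkit.motifs import (
    TRIAD_REPRESENTATIVES,
    brute_force_census,
    classify_triad,
    degree_preserving_randomize,
    ensemble_stats,
    motif_profile,
    significance_profile,
    triad_census,
    zscores,
    RandomEnsembleStats,
    TriadCensus,
)
from trnkit.synthetic import (
    CENSUS10_EXPECTED,
    SyntheticSpec,
    generate_trn,
    plant_motifs,
)

from conftest import random_digraph, structural_net


class TestClassifyTriad:
    def test_feed_forward_loop_is_id_7(self):
        assert classify_triad([("X", "Y"), ("X", "Z"), ("Y", "Z")]) == 7

    def test_mutual_pair_common_target_is_id_10(self):
        assert classify_triad([("X", "Y"), ("Y", "X"), ("X", "Z"), ("Y", "Z")]) == 10

    def test_single_edge_triple_is_disconnected(self):
        assert classify_triad([("X", "Y")], nodes=["X", "Y", "Z"]) == "disconnected"

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            classify_triad([("X", "X"), ("X", "Y"), ("Y", "Z")])

    def test_invariant_under_node_relabeling(self):
        """All 6 node permutations of every representative give its own id."""
        for display_id, (_, edges) in TRIAD_REPRESENTATIVES.items():
            for perm in permutations("abc"):
                relabeled = [(perm[u], perm[v]) for u, v in edges]
                assert classify_triad(relabeled, nodes=list("abc")) == display_id


class TestTriadCensus:
    def test_empty_network_all_zero(self):
        census = triad_census(structural_net([("A", "B")]))
        assert census.n_connected_triples == 0

    def test_single_ffl(self, tiny_nets):
        assert triad_census(tiny_nets["ffl"]).counts[7] == 1
        assert triad_census(tiny_nets["ffl"]).n_connected_triples == 1

    def test_census10_fixture_matches_committed_hand_count(self, tiny_nets):
        assert dict(triad_census(tiny_nets["census10"]).counts) == CENSUS10_EXPECTED

    def test_matches_brute_force_on_random_digraph(self):
        g = random_digraph(25, 0.15, seed=77)
        assert triad_census(g).counts == brute_force_census(g).counts

    def test_self_loops_stripped_before_census(self):
        with_loop = structural_net([("X", "Y"), ("X", "Z"), ("Y", "Z"), ("X", "X")])
        assert triad_census(with_loop).counts[7] == 1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.tuples(st.integers(0, 11), st.integers(0, 11)).filter(
                lambda e: e[0] != e[1]
            ),
            max_size=60,
        )
    )
    def test_fast_census_equals_oracle(self, edges):
        g = nx.DiGraph()
        g.add_nodes_from(range(12))
        g.add_edges_from(edges)
        assert triad_census(g).counts == brute_force_census(g).counts


class TestRandomizer:
    @staticmethod
    def degree_sequences(g: nx.DiGraph):
        return (dict(g.in_degree()), dict(g.out_degree()))

    def test_degree_sequences_preserved(self):
        net, _ = generate_trn(SyntheticSpec(n_tf=15, n_tg=120, seed=8))
        g = net.to_digraph()
        for seed in range(5):
            h = degree_preserving_randomize(g, seed=seed)
            assert self.degree_sequences(h) == self.degree_sequences(g)
            assert h.number_of_edges() == g.number_of_edges()

    def test_two_edge_path_is_a_fixed_point(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        h = degree_preserving_randomize(g, swap_factor=50, seed=1)
        assert set(h.edges()) == {("A", "B"), ("B", "C")}

    def test_seed_determinism_and_seed_sensitivity(self):
        net, _ = generate_trn(SyntheticSpec(n_tf=15, n_tg=100, seed=23))
        g = net.to_digraph()
        assert g.number_of_edges() >= 200
        same1 = degree_preserving_randomize(g, seed=5)
        same2 = degree_preserving_randomize(g, seed=5)
        other = degree_preserving_randomize(g, seed=6)
        assert set(same1.edges()) == set(same2.edges())
        assert set(same1.edges()) != set(other.edges())

    def test_preserve_mutual_keeps_mutual_dyad_count(self):
        edges = [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C"),
                 ("A", "C"), ("B", "D"), ("D", "E"), ("E", "F"),
                 ("F", "A"), ("C", "E"), ("E", "B"), ("F", "C")]
        g = nx.DiGraph(edges)

        def n_mutual(h):
            return sum((v, u) in h.edges() for u, v in h.edges()) // 2

        for seed in range(5):
            h = degree_preserving_randomize(g, seed=seed, preserve_mutual=True)
            assert n_mutual(h) == n_mutual(g)

    def test_network_input_returns_structural_network(self, tiny_nets):
        out = degree_preserving_randomize(tiny_nets["census10"], seed=3)
        assert len(out) == len(tiny_nets["census10"])

    def test_invalid_swap_factor(self, tiny_nets):
        with pytest.raises(ValueError):
            degree_preserving_randomize(tiny_nets["ffl"], swap_factor=0, seed=1)


class TestEnsembleAndScores:
    def test_single_replicate_has_zero_std(self, tiny_nets):
        stats = ensemble_stats(tiny_nets["census10"], R=1, base_seed=4)
        assert all(s == 0.0 for s in stats.std.values())

    def test_ffl_ensemble_conserves_triple_count(self, tiny_nets):
        stats = ensemble_stats(tiny_nets["ffl"], R=20, base_seed=0)
        assert sum(stats.mean.values()) == pytest.approx(1.0)

    def test_reproducible_under_same_base_seed(self):
        net, _ = generate_trn(
            SyntheticSpec(n_tf=10, n_tg=50, planted_motifs=((7, 5),), seed=60)
        )
        a = ensemble_stats(net, R=50, base_seed=99)
        b = ensemble_stats(net, R=50, base_seed=99)
        assert a == b

    def test_zscore_rules(self):
        ens = RandomEnsembleStats(
            mean={i: 4.0 for i in range(1, 14)},
            std={i: 2.0 if i != 3 else 0.0 for i in range(1, 14)},
            R=10,
            base_seed=0,
        )
        counts = {i: 0 for i in range(1, 14)}
        counts.update({1: 10, 2: 3, 3: 5})
        z = zscores(TriadCensus(counts=counts), ens)
        assert z[1] == pytest.approx(3.0)  # (10 - 4) / 2
        assert z[2] == 0.0  # fewer than 4 occurrences
        assert z[3] == 0.0  # degenerate ensemble std


class TestSignificanceProfile:
    def test_three_four_five_triangle(self):
        z = {i: 0.0 for i in range(1, 14)}
        z.update({1: 3.0, 2: 4.0})
        sp = significance_profile(z).sp
        assert sp[1] == pytest.approx(0.6)
        assert sp[2] == pytest.approx(0.8)

    def test_unit_norm_for_any_nonzero_input(self):
        rng = np.random.default_rng(3)
        z = {i: float(v) for i, v in zip(range(1, 14), rng.normal(size=13))}
        sp = significance_profile(z).sp
        assert sum(v * v for v in sp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_maps_to_all_zero(self):
        sp = significance_profile({i: 0.0 for i in range(1, 14)}).sp
        assert all(v == 0.0 for v in sp.values())


class TestMotifProfile:
    def test_network_without_triads_gives_zero_profile(self):
        net = structural_net([("A", "B"), ("C", "D")])
        prof = motif_profile([net], R=10, base_seed=0)
        assert (prof.to_numpy() == 0).all()

    def test_planted_ffl_enrichment_is_positive(self):
        net, _ = generate_trn(
            SyntheticSpec(
                n_tf=8, n_tg=40, in_degree_law=("geometric", 0.6),
                planted_motifs=((7, 30),), seed=5,
            )
        )
        prof = motif_profile([net], R=200, base_seed=11)
        assert prof.loc[net.label, "sp_7"] > 0

    def test_identical_networks_give_identical_profiles(self, tiny_nets):
        net = tiny_nets["census10"]
        prof = motif_profile([net, net], R=50, base_seed=7, labels=["a", "b"])
        assert prof.loc["a"].tolist() == prof.loc["b"].tolist()

    def test_planted_id10_recovered_in_census(self):
        background, _ = generate_trn(SyntheticSpec(n_tf=6, n_tg=30, seed=19))
        planted, ledger = plant_motifs(background, display_id=10, count=10, seed=2)
        assert triad_census(planted).counts[10] >= 10
        assert len(ledger.planted[10]) == 10
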