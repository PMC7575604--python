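"""Network model: I/O, merging, evidence algebra and summary statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trnkit as tk
from trnkit.io import read_network, write_network
from trnkit.network import (
    EvidencePartition,
    Interaction,
    NetworkSummary,
    OverlapStats,
    RegulatoryNetwork,
    Sign,
    aggregate_sign,
)
from trnkit.synthetic import SyntheticSpec, generate_trn

TSV_HEADER = "tf\ttarget\tevidence\tsign\tconditions\treferences\n"


class TestReadWrite:
    def test_duplicate_rows_merge(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text(
            TSV_HEADER
            + "A\tg1\tbinding\t\t\tR1\n"
            + "A\tg1\texpression\tpositive\tStress\tR2\n"
            + "B\tg2\texpression\tnegative\t\tR1\n"
        )
        net = read_network(f)
        assert len(net) == 2
        merged = net[("A", "G1")]
        assert merged.has_binding and merged.has_expression
        assert merged.sign is Sign.POSITIVE
        assert merged.references == {"R1", "R2"}

    def test_rows_without_evidence_dropped(self, tmp_path, caplog):
        f = tmp_path / "net.tsv"
        f.write_text(TSV_HEADER + "A\tg1\t\t\t\t\n")
        with caplog.at_level("WARNING"):
            net = read_network(f)
        assert len(net) == 0
        assert "dropped 1" in caplog.text

    def test_unknown_evidence_token_lists_vocabulary(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text(TSV_HEADER + "A\tg1\tchip-seq\t\t\t\n")
        with pytest.raises(ValueError, match="binding.*expression"):
            read_network(f)

    def test_malformed_row_names_line(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text(TSV_HEADER + "A\tg1\tbinding\t\t\t\n\tg2\tbinding\t\t\t\n")
        with pytest.raises(ValueError, match=":3"):
            read_network(f)

    def test_round_trip_identity(self, tmp_path, three_row_net, tiny_nets):
        for net in (three_row_net, tiny_nets["mini_venn"]):
            p = tmp_path / "out.tsv"
            write_network(net, p)
            assert read_network(p, label=net.label) == net

    def test_write_is_byte_deterministic(self, tmp_path, tiny_nets):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_network(tiny_nets["mini_venn"], p1)
        write_network(tiny_nets["mini_venn"], p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_network_writes_header_only(self, tmp_path):
        p = write_network(RegulatoryNetwork(), tmp_path / "empty.tsv")
        assert p.read_text() == TSV_HEADER

    def test_edge_list_defaults_to_binding(self, tmp_path):
        f = tmp_path / "edges.tsv"
        f.write_text("tfa\tgene1\ntfb\tgene2\n")
        net = tk.read_edge_list(f)
        assert len(net) == 2
        assert all(it.has_binding and not it.has_expression for it in net.interactions)


class TestAggregateSign:
    @pytest.mark.parametrize(
        "observed, expected",
        [
            ([Sign.POSITIVE, Sign.POSITIVE], Sign.POSITIVE),
            ([Sign.NEGATIVE, Sign.NEGATIVE], Sign.NEGATIVE),
            ([Sign.POSITIVE, Sign.NEGATIVE], Sign.DUAL),
            ([Sign.DUAL], Sign.DUAL),
            ([Sign.POSITIVE, Sign.DUAL], Sign.DUAL),
            ([Sign.UNKNOWN], Sign.UNKNOWN),
            ([Sign.UNKNOWN, Sign.NEGATIVE], Sign.NEGATIVE),
            ([Sign.UNKNOWN, Sign.POSITIVE, Sign.UNKNOWN], Sign.POSITIVE),
        ],
    )
    def test_aggregation_rule(self, observed, expected):
        assert aggregate_sign(observed) is expected

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValueError):
            aggregate_sign([])


class TestEvidenceFiltering:
    def test_b_and_e_keeps_doubly_supported_only(self, three_row_net):
        both = tk.filter_by_evidence(three_row_net, "B_and_E")
        assert both.pairs == {("A", "G1")}

    def test_b_on_expression_only_network_is_empty(self):
        net = RegulatoryNetwork.from_interactions(
            [Interaction(tf="A", target="G", has_expression=True, sign=Sign.UNKNOWN)]
        )
        assert len(tk.filter_by_evidence(net, "B")) == 0

    def test_unknown_selector_rejected(self, three_row_net):
        with pytest.raises(ValueError):
            tk.filter_by_evidence(three_row_net, "B_xor_E")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 5), st.integers(0, 12),
                st.sampled_from([(True, False), (False, True), (True, True)]),
            ),
            min_size=1, max_size=40, unique_by=lambda t: (t[0], t[1]),
        )
    )
    def test_inclusion_exclusion(self, rows):
        """|B| + |E| - |B&E| = |B|E| for any evidence assignment."""
        net = RegulatoryNetwork.from_interactions(
            Interaction(
                tf=f"T{t}", target=f"G{g}", has_binding=b, has_expression=e,
                sign=Sign.UNKNOWN if e else Sign.NOT_APPLICABLE,
            )
            for t, g, (b, e) in rows
        )
        n = {
            sel: len(tk.filter_by_evidence(net, sel))
            for sel in ("B", "E", "B_and_E", "B_or_E")
        }
        assert n["B"] + n["E"] - n["B_and_E"] == n["B_or_E"]
        assert n["B_or_E"] == len(net)

    def test_no_isolated_nodes_after_filtering(self, three_row_net):
        sub = tk.filter_by_evidence(three_row_net, "B_and_E")
        assert sub.nodes == {"A", "G1"}


class TestConditionFiltering:
    def test_direct_selection_and_identity(self):
        net = RegulatoryNetwork.from_interactions(
            Interaction(
                tf=f"T{i}", target=f"G{i}", has_binding=True,
                conditions=frozenset(["Stress"] if i < 2 else []) | {"All"},
            )
            for i in range(5)
        )
        assert len(tk.filter_by_condition(net, "Stress")) == 2
        assert tk.filter_by_condition(net, "All").pairs == net.pairs

    def test_unknown_tag_gives_empty_network(self, three_row_net, caplog):
        with caplog.at_level("WARNING"):
            sub = tk.filter_by_condition(three_row_net, "no-such-tag")
        assert len(sub) == 0

    def test_synthetic_counts_match_generator_ledger(self):
        net, ledger = generate_trn(
            SyntheticSpec(n_tf=40, n_tg=1000, condition_rates={"Stress": 0.3}, seed=11)
        )
        assert len(tk.filter_by_condition(net, "Stress")) == ledger.condition_count(
            "Stress"
        )


class TestSummarize:
    def test_density_from_counts(self):
        s = NetworkSummary.from_counts(
            n_nodes=3937, n_interactions=11486, n_tfs=152, n_tgs=3912
        )
        assert s.n_possible == 598424
        assert s.density_pct == 1.92

    def test_single_interaction_density(self):
        net = RegulatoryNetwork.from_interactions(
            [Interaction(tf="A", target="B", has_binding=True)]
        )
        assert tk.summarize(net).density_pct == 50.00

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            tk.summarize(RegulatoryNetwork())


class TestVennPartition:
    def test_all_binding_network(self, tiny_nets):
        v = tk.venn_partition(tiny_nets["ffl"])
        assert (v.pct_expression_only, v.pct_binding_only, v.pct_both) == (0, 100, 0)

    def test_percentages_sum_to_100(self, tiny_nets):
        v = tk.venn_partition(tiny_nets["mini_venn"])
        total = v.pct_expression_only + v.pct_binding_only + v.pct_both
        assert abs(total - 100) <= 0.02

    def test_synthetic_partition_matches_ledger_exactly(self):
        net, ledger = generate_trn(
            SyntheticSpec(
                n_tf=60, n_tg=2000, evidence_fractions=(0.7, 0.2, 0.1), seed=5
            )
        )
        assert len(net) >= 5000 or len(net) > 0
        v = tk.venn_partition(net)
        assert (
            v.n_expression_only, v.n_binding_only, v.n_both
        ) == ledger.venn_counts()

    def test_sign_tallies_cover_expression_supported(self, tiny_nets):
        v = tk.venn_partition(tiny_nets["mini_venn"])
        assert sum(v.sign_tallies.values()) == v.n_expression_only + v.n_both

    def test_from_set_sizes_validates(self):
        with pytest.raises(ValueError):
            EvidencePartition.from_set_sizes(n_b=5, n_e=10, n_both=7)


class TestOverlap:
    def test_self_overlap_is_total(self, three_row_net):
        o = tk.overlap(three_row_net, three_row_net)
        assert o.n_common == len(three_row_net)
        assert o.pct_of_a == o.pct_of_b == 100.0

    def test_symmetry_of_common_count(self, three_row_net, tiny_nets):
        a, b = three_row_net, tiny_nets["ffl"]
        assert tk.overlap(a, b).n_common == tk.overlap(b, a).n_common

    def test_partial_overlap(self, tmp_path):
        a = RegulatoryNetwork.from_interactions(
            [Interaction(tf="A", target="B", has_binding=True),
             Interaction(tf="A", target="C", has_binding=True)]
        )
        b = RegulatoryNetwork.from_interactions(
            [Interaction(tf="A", target="B", has_expression=True, sign=Sign.UNKNOWN)]
        )
        o = tk.overlap(a, b)
        assert (o.n_common, o.pct_of_a, o.pct_of_b) == (1, 50.0, 100.0)


class TestReferenceSupport:
    def test_single_reference_each(self):
        net = RegulatoryNetwork.from_interactions(
            Interaction(
                tf="A", target=f"G{i}", has_binding=True,
                references=frozenset({f"R{i % 2}"}),
            )
            for i in range(4)
        )
        stats = tk.reference_support_stats(net)
        assert stats.mean_references_per_interaction == 1.0
        assert stats.per_reference_exclusive == stats.per_reference_counts

    def test_synthetic_means_match_ledger(self):
        net, ledger = generate_trn(
            SyntheticSpec(n_tf=40, n_tg=2000, reference_mu=0.6, seed=3)
        )
        stats = tk.reference_support_stats(net)
        assert stats.mean_references_per_interaction == pytest.approx(
            ledger.mean_references_per_interaction()
        )
        assert stats.mean_interactions_per_reference == pytest.approx(
            ledger.mean_interactions_per_reference()
        )
        total = sum(stats.per_reference_counts.values())
        assert total == sum(len(it.references) for it in net.interactions)
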