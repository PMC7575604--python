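"""Data model and set algebra for evidence-annotated transcriptional regulatory networks.

A regulatory association links a transcription factor (TF) to a target gene
(TG) and carries the experimental evidence behind it: *binding* evidence (the
TF was shown to occupy the gene's promoter, e.g. by ChIP-on-chip, ChIP-seq,
EMSA or footprinting) and/or *expression* evidence (perturbing the TF changed
the target's transcript level).  Expression evidence additionally attributes a
sign to the association — positive (activation), negative (repression), dual
(both reported) or unknown (a change without directionality).

Evidence is stored as two orthogonal booleans so that the classical evidence
sets compose by plain set algebra:

    B      associations with binding evidence
    E      associations with expression evidence
    B&E    both kinds of evidence
    B|E    at least one kind (the full network)

which guarantees the inclusion–exclusion identity |B| + |E| − |B&E| = |B|E|.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Sign",
    "EvidenceSelector",
    "Interaction",
    "RegulatoryNetwork",
    "NetworkSummary",
    "EvidencePartition",
    "ReferenceSupportStats",
    "OverlapStats",
    "aggregate_sign",
    "filter_by_evidence",
    "filter_by_condition",
    "summarize",
    "venn_partition",
    "overlap",
    "reference_support_stats",
    "pct",
]


def pct(numerator: float, denominator: float) -> float:
    """Percentage rounded half-even to 2 decimals (table convention)."""
    return round(100.0 * numerator / denominator, 2)


class Sign(str, enum.Enum):
    """Aggregated regulatory effect of a TF on its target."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    DUAL = "dual"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


class EvidenceSelector(str, enum.Enum):
    """The four evidence-defined association sets."""

    B = "B"
    E = "E"
    B_OR_E = "B_or_E"
    B_AND_E = "B_and_E"


def normalize_gene(name: str) -> str:
    """Uppercase, whitespace-stripped gene identifier (exact-match semantics)."""
    return name.strip().upper()


@dataclass(frozen=True)
class Interaction:
    """One TF→TG association with its merged annotation.

    ``has_binding``/``has_expression`` record whether at least one supporting
    publication provides that kind of evidence.  ``sign`` is the aggregate
    over all expression-evidence publications; it is ``NOT_APPLICABLE`` iff
    the association has no expression evidence.
    """

    tf: str
    target: str
    has_binding: bool = False
    has_expression: bool = False
    sign: Sign = Sign.NOT_APPLICABLE
    conditions: frozenset[str] = frozenset()
    references: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.has_binding or self.has_expression):
            raise ValueError(
                f"{self.tf}->{self.target}: an association must carry binding "
                "or expression evidence"
            )
        if self.sign is not Sign.NOT_APPLICABLE and not self.has_expression:
            raise ValueError(
                f"{self.tf}->{self.target}: a sign requires expression evidence"
            )
        if self.has_expression and self.sign is Sign.NOT_APPLICABLE:
            raise ValueError(
                f"{self.tf}->{self.target}: expression evidence requires a sign "
                "(use Sign.UNKNOWN when no directionality was reported)"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf, self.target)


def aggregate_sign(observed: Iterable[Sign | str]) -> Sign:
    """Aggregate per-publication signs into the association-level sign.

    All-positive observations give ``POSITIVE``; all-negative give
    ``NEGATIVE``; conflicting directional observations, or any explicit
    ``DUAL``, give ``DUAL``.  Undirected (``UNKNOWN``) observations never
    override a consistent directional sign; only-unknown gives ``UNKNOWN``.
    """
    signs = {Sign(s) for s in observed}
    if not signs:
        raise ValueError("aggregate_sign requires at least one observation")
    if Sign.NOT_APPLICABLE in signs:
        raise ValueError("NOT_APPLICABLE is not an observable sign")
    if Sign.DUAL in signs or {Sign.POSITIVE, Sign.NEGATIVE} <= signs:
        return Sign.DUAL
    if Sign.POSITIVE in signs:
        return Sign.POSITIVE
    if Sign.NEGATIVE in signs:
        return Sign.NEGATIVE
    return Sign.UNKNOWN


@dataclass
class RegulatoryNetwork:
    """A deduplicated set of TF→TG associations.

    The (tf, target) pair is the identity: annotations from duplicate records
    merge.  Node, TF and TG sets are derived from the interactions, so no
    node is ever isolated.
    """

    label: str = ""
    _by_pair: dict[tuple[str, str], Interaction] = field(default_factory=dict)

    @classmethod
    def from_interactions(
        cls, interactions: Iterable[Interaction], label: str = ""
    ) -> "RegulatoryNetwork":
        net = cls(label=label)
        for it in interactions:
            net.add(it)
        return net

    def add(self, interaction: Interaction) -> None:
        """Insert an interaction, merging with an existing (tf, target) record."""
        key = interaction.pair
        old = self._by_pair.get(key)
        if old is None:
            self._by_pair[key] = interaction
            return
        has_expression = old.has_expression or interaction.has_expression
        observed = [
            it.sign
            for it in (old, interaction)
            if it.sign is not Sign.NOT_APPLICABLE
        ]
        sign = aggregate_sign(observed) if has_expression else Sign.NOT_APPLICABLE
        self._by_pair[key] = Interaction(
            tf=old.tf,
            target=old.target,
            has_binding=old.has_binding or interaction.has_binding,
            has_expression=has_expression,
            sign=sign,
            conditions=old.conditions | interaction.conditions,
            references=old.references | interaction.references,
        )

    @property
    def interactions(self) -> list[Interaction]:
        """Interactions in deterministic (tf, target) order."""
        return [self._by_pair[k] for k in sorted(self._by_pair)]

    def __len__(self) -> int:
        return len(self._by_pair)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._by_pair

    def __getitem__(self, pair: tuple[str, str]) -> Interaction:
        return self._by_pair[pair]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._by_pair == other._by_pair

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._by_pair)

    @property
    def nodes(self) -> set[str]:
        return self.tfs | self.tgs

    @property
    def tfs(self) -> set[str]:
        """Nodes with out-degree ≥ 1."""
        return {tf for tf, _ in self._by_pair}

    @property
    def tgs(self) -> set[str]:
        """Nodes with in-degree ≥ 1."""
        return {tg for _, tg in self._by_pair}

    def to_digraph(self, strip_self_loops: bool = False):
        """Directed graph over the interaction pairs (annotation dropped)."""
        import networkx as nx

        g = nx.DiGraph()
        for tf, tg in sorted(self._by_pair):
            if strip_self_loops and tf == tg:
                continue
            g.add_edge(tf, tg)
        return g


@dataclass(frozen=True)
class NetworkSummary:
    """Node/interaction/TF/TG counts and the realized fraction of possible
    interactions (every identified TF regulating every node)."""

    label: str
    n_nodes: int
    n_interactions: int
    n_tfs: int
    n_tgs: int
    density_pct: float

    @property
    def n_possible(self) -> int:
        return self.n_tfs * self.n_nodes

    @classmethod
    def from_counts(
        cls,
        n_nodes: int,
        n_interactions: int,
        n_tfs: int,
        n_tgs: int,
        label: str = "",
    ) -> "NetworkSummary":
        if n_tfs > n_nodes or n_tgs > n_nodes:
            raise ValueError("TF/TG counts cannot exceed the node count")
        return cls(
            label=label,
            n_nodes=n_nodes,
            n_interactions=n_interactions,
            n_tfs=n_tfs,
            n_tgs=n_tgs,
            density_pct=pct(n_interactions, n_tfs * n_nodes),
        )


def summarize(net: RegulatoryNetwork) -> NetworkSummary:
    """Table-style summary of a network (counts and density percentage)."""
    if len(net) == 0:
        raise ValueError("cannot summarize an empty network (density undefined)")
    return NetworkSummary.from_counts(
        n_nodes=len(net.nodes),
        n_interactions=len(net),
        n_tfs=len(net.tfs),
        n_tgs=len(net.tgs),
        label=net.label,
    )


def filter_by_evidence(
    net: RegulatoryNetwork, selector: EvidenceSelector | str
) -> RegulatoryNetwork:
    """Restrict a network to one of the evidence sets B, E, B&E or B|E."""
    selector = EvidenceSelector(selector)
    keep = {
        EvidenceSelector.B: lambda it: it.has_binding,
        EvidenceSelector.E: lambda it: it.has_expression,
        EvidenceSelector.B_AND_E: lambda it: it.has_binding and it.has_expression,
        EvidenceSelector.B_OR_E: lambda it: True,
    }[selector]
    label = f"{net.label}[{selector.value}]" if net.label else selector.value
    return RegulatoryNetwork.from_interactions(
        (it for it in net.interactions if keep(it)), label=label
    )


def filter_by_condition(net: RegulatoryNetwork, condition: str) -> RegulatoryNetwork:
    """Keep interactions observed under the given environmental condition tag."""
    surviving = [it for it in net.interactions if condition in it.conditions]
    if not surviving:
        logger.warning(
            "condition %r matches no interaction in network %r", condition, net.label
        )
    label = f"{net.label}[{condition}]" if net.label else condition
    return RegulatoryNetwork.from_interactions(surviving, label=label)


@dataclass(frozen=True)
class EvidencePartition:
    """Venn partition of associations into expression-only / binding-only /
    doubly-supported classes, with percentages of the union."""

    n_expression_only: int
    n_binding_only: int
    n_both: int
    sign_tallies: Mapping[Sign, int] = field(default_factory=dict)

    @property
    def n_union(self) -> int:
        return self.n_expression_only + self.n_binding_only + self.n_both

    @property
    def pct_expression_only(self) -> float:
        return pct(self.n_expression_only, self.n_union)

    @property
    def pct_binding_only(self) -> float:
        return pct(self.n_binding_only, self.n_union)

    @property
    def pct_both(self) -> float:
        return pct(self.n_both, self.n_union)

    @classmethod
    def from_set_sizes(cls, n_b: int, n_e: int, n_both: int) -> "EvidencePartition":
        """Build from the sizes of the evidence sets B, E and B&E."""
        if n_both > min(n_b, n_e):
            raise ValueError("|B&E| cannot exceed |B| or |E|")
        return cls(
            n_expression_only=n_e - n_both,
            n_binding_only=n_b - n_both,
            n_both=n_both,
        )


def venn_partition(net: RegulatoryNetwork) -> EvidencePartition:
    """Partition a network's interactions by evidence class.

    Sign tallies are computed over the expression-supported interactions
    (signs can only come from expression evidence).
    """
    n_e_only = n_b_only = n_both = 0
    tallies: Counter[Sign] = Counter()
    for it in net.interactions:
        if it.has_binding and it.has_expression:
            n_both += 1
        elif it.has_binding:
            n_b_only += 1
        else:
            n_e_only += 1
        if it.has_expression:
            tallies[it.sign] += 1
    return EvidencePartition(
        n_expression_only=n_e_only,
        n_binding_only=n_b_only,
        n_both=n_both,
        sign_tallies=dict(tallies),
    )


@dataclass(frozen=True)
class OverlapStats:
    """Size of the pairwise interaction intersection of two networks,
    as counts and as percentages of each network."""

    n_common: int
    n_a: int
    n_b: int
    label_a: str = ""
    label_b: str = ""

    @property
    def pct_of_a(self) -> float:
        return pct(self.n_common, self.n_a)

    @property
    def pct_of_b(self) -> float:
        return pct(self.n_common, self.n_b)


def overlap(a: RegulatoryNetwork, b: RegulatoryNetwork) -> OverlapStats:
    """Interaction overlap of two networks, matching on the (tf, target) pair."""
    common = a.pairs & b.pairs
    return OverlapStats(
        n_common=len(common),
        n_a=len(a),
        n_b=len(b),
        label_a=a.label,
        label_b=b.label,
    )


@dataclass(frozen=True)
class ReferenceSupportStats:
    """Literature support of a network: how many interactions each reference
    documents, how many of those no other reference documents, and the two
    global means."""

    per_reference_counts: Mapping[str, int]
    per_reference_exclusive: Mapping[str, int]
    mean_interactions_per_reference: float
    mean_references_per_interaction: float

    def share_pct(self, reference: str, n_interactions: int) -> float:
        """Percentage of the network's interactions this reference documents."""
        return pct(self.per_reference_counts.get(reference, 0), n_interactions)


def reference_support_stats(net: RegulatoryNetwork) -> ReferenceSupportStats:
    counts: Counter[str] = Counter()
    exclusive: Counter[str] = Counter()
    total_refs = 0
    for it in net.interactions:
        total_refs += len(it.references)
        for ref in it.references:
            counts[ref] += 1
        if len(it.references) == 1:
            (only,) = it.references
            exclusive[only] += 1
    n_refs = len(counts)
    return ReferenceSupportStats(
        per_reference_counts=dict(counts),
        per_reference_exclusive={r: exclusive.get(r, 0) for r in counts},
        mean_interactions_per_reference=(total_refs / n_refs) if n_refs else 0.0,
        mean_references_per_interaction=(total_refs / len(net)) if len(net) else 0.0,
    )
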