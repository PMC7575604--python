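"""Synthetic evidence-annotated regulatory networks for testing and benchmarks.

Real transcriptional networks combine a heavy-tailed out-degree distribution
(a few master regulators control hundreds of genes) with a light-tailed
in-degree distribution (most genes have a handful of regulators).  The
generator emulates this: TF out-degrees are drawn from a discrete power law
(or fixed), TG in-degrees from a geometric (or shifted Poisson) law, and the
network is wired bipartitely, each target gene sampling its drawn number of
distinct regulators with out-degree-proportional weights.  Each realized interaction is then annotated with
an evidence class, a sign, condition tags and reference identifiers drawn
from configurable fractions; specific triad classes can be planted on
disjoint fresh nodes for enrichment power studies.

Every random assignment is recorded in a :class:`GeneratorLedger`, which
fully determines the emitted network and serves as the independent oracle
for downstream summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .motifs import TRIAD_REPRESENTATIVES
from .network import Interaction, RegulatoryNetwork, Sign

__all__ = [
    "SyntheticSpec",
    "GeneratorLedger",
    "generate_trn",
    "plant_motifs",
    "fixtures",
    "CENSUS10_EXPECTED",
]

#: Evidence-class fractions (expression-only, binding-only, both) matching the
#: published Venn partition of the yeast network compendium.
DEFAULT_EVIDENCE_FRACTIONS = (0.7687, 0.1725, 0.0588)

#: Sign fractions (positive, negative, dual, unknown) for expression-supported
#: interactions: activation dominates curated yeast data, dual effects are rare.
DEFAULT_SIGN_FRACTIONS = (0.55, 0.30, 0.05, 0.10)

DEFAULT_CONDITION_RATES = {
    "Stress": 0.3,
    "Unstressed log-phase growth (control)": 0.5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters of a synthetic annotated regulatory network."""

    n_tf: int = 150
    n_tg: int = 2000
    out_degree_law: tuple = ("power_law", 2.0)  # or ("uniform", k)
    in_degree_law: tuple = ("geometric", 0.35)  # or ("poisson", lam)
    evidence_fractions: tuple[float, float, float] = DEFAULT_EVIDENCE_FRACTIONS
    sign_fractions: tuple[float, float, float, float] = DEFAULT_SIGN_FRACTIONS
    condition_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_RATES)
    )
    reference_mu: float = 0.61  # refs per interaction = 1 + Poisson(mu)
    n_references: int = 200
    planted_motifs: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tf <= 0 or self.n_tg <= 0:
            raise ValueError("n_tf and n_tg must be positive")
        if abs(sum(self.evidence_fractions) - 1.0) > 1e-9:
            raise ValueError("evidence_fractions must sum to 1")
        if abs(sum(self.sign_fractions) - 1.0) > 1e-9:
            raise ValueError("sign_fractions must sum to 1")
        for display_id, count in self.planted_motifs:
            if display_id not in TRIAD_REPRESENTATIVES:
                raise ValueError(f"unknown triad display id {display_id}")
            if count < 0:
                raise ValueError("planted motif count must be non-negative")
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")


@dataclass
class GeneratorLedger:
    """Exact bookkeeping of every random draw behind a synthetic network."""

    drawn_out_degrees: list[int] = field(default_factory=list)
    drawn_in_degrees: list[int] = field(default_factory=list)
    evidence_class: dict[tuple[str, str], str] = field(default_factory=dict)
    signs: dict[tuple[str, str], str] = field(default_factory=dict)
    conditions: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    references: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)
    planted: dict[int, list[tuple[str, str, str]]] = field(default_factory=dict)

    def venn_counts(self) -> tuple[int, int, int]:
        """(expression_only, binding_only, both) recomputed from the ledger."""
        vals = list(self.evidence_class.values())
        return (
            vals.count("expression_only"),
            vals.count("binding_only"),
            vals.count("both"),
        )

    def condition_count(self, tag: str) -> int:
        return sum(tag in tags for tags in self.conditions.values())

    def mean_references_per_interaction(self) -> float:
        return float(np.mean([len(r) for r in self.references.values()]))

    def mean_interactions_per_reference(self) -> float:
        total = sum(len(r) for r in self.references.values())
        distinct = {ref for refs in self.references.values() for ref in refs}
        return total / len(distinct)

    def expected_in_degree_mean(self) -> float:
        return float(np.mean(self.drawn_in_degrees))


def _draw_out_degrees(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    law, param = spec.out_degree_law
    if law == "power_law":
        draws = stats.zipf.rvs(param, size=spec.n_tf, random_state=rng)
        return np.minimum(draws, spec.n_tg)
    if law == "uniform":
        return np.full(spec.n_tf, int(param))
    raise ValueError(f"unknown out-degree law {law!r}")


def _draw_in_degrees(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    law, param = spec.in_degree_law
    if law == "geometric":
        return rng.geometric(param, size=spec.n_tg)
    if law == "poisson":
        # shifted so no target gene is isolated
        return 1 + rng.poisson(param, size=spec.n_tg)
    raise ValueError(f"unknown in-degree law {law!r}")


def _annotate(
    tf: str,
    tg: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    ledger: GeneratorLedger,
    ref_pool: list[str],
) -> Interaction:
    cls = ("expression_only", "binding_only", "both")[
        rng.choice(3, p=spec.evidence_fractions)
    ]
    has_binding = cls in ("binding_only", "both")
    has_expression = cls in ("expression_only", "both")
    if has_expression:
        sign = (Sign.POSITIVE, Sign.NEGATIVE, Sign.DUAL, Sign.UNKNOWN)[
            rng.choice(4, p=spec.sign_fractions)
        ]
    else:
        sign = Sign.NOT_APPLICABLE
    tags = tuple(
        tag
        for tag, rate in sorted(spec.condition_rates.items())
        if rng.random() < rate
    )
    n_refs = min(1 + rng.poisson(spec.reference_mu), len(ref_pool))
    refs = tuple(sorted(rng.choice(ref_pool, size=n_refs, replace=False)))
    pair = (tf, tg)
    ledger.evidence_class[pair] = cls
    ledger.signs[pair] = sign.value
    ledger.conditions[pair] = tags
    ledger.references[pair] = refs
    return Interaction(
        tf=tf,
        target=tg,
        has_binding=has_binding,
        has_expression=has_expression,
        sign=sign,
        conditions=frozenset(tags),
        references=frozenset(refs),
    )


def generate_trn(spec: SyntheticSpec) -> tuple[RegulatoryNetwork, GeneratorLedger]:
    """Generate a seed-deterministic annotated regulatory network.

    Degrees are drawn from the spec's laws and realized bipartitely in a
    configuration-style manner: each target gene receives exactly its drawn
    in-degree (capped at the TF count) by sampling that many *distinct* TFs
    with probability proportional to the TF's drawn out-degree, so the
    in-degree law is reproduced faithfully while out-degrees inherit the
    heavy tail of the out-degree law.  Realized TF out-degrees therefore
    differ from the drawn targets; the ledger records the drawn values and
    all realized quantities are recomputable from the emitted network.
    Planted motif instances sit on disjoint fresh nodes.
    """
    rng = np.random.default_rng(spec.seed)
    ledger = GeneratorLedger()

    out_deg = _draw_out_degrees(spec, rng)
    in_deg = _draw_in_degrees(spec, rng)
    ledger.drawn_out_degrees = [int(d) for d in out_deg]
    ledger.drawn_in_degrees = [int(d) for d in in_deg]

    tf_names = [f"TF{i:04d}" for i in range(spec.n_tf)]
    tg_names = [f"G{j:05d}" for j in range(spec.n_tg)]
    weights = out_deg / out_deg.sum()

    ref_pool = [f"R{k:04d}" for k in range(spec.n_references)]
    net = RegulatoryNetwork(label=f"synthetic(seed={spec.seed})")
    for j, d in enumerate(in_deg):
        regulators = rng.choice(
            spec.n_tf, size=min(int(d), spec.n_tf), replace=False, p=weights
        )
        for i in sorted(regulators):
            net.add(_annotate(tf_names[i], tg_names[j], spec, rng, ledger, ref_pool))

    for display_id, count in spec.planted_motifs:
        _plant(net, display_id, count, rng, spec, ledger, ref_pool)
    if len(net) == 0:
        raise ValueError("spec produced an empty network")
    return net, ledger


def _plant(
    net: RegulatoryNetwork,
    display_id: int,
    count: int,
    rng: np.random.Generator,
    spec: SyntheticSpec | None,
    ledger: GeneratorLedger,
    ref_pool: list[str] | None,
) -> None:
    _, edges = TRIAD_REPRESENTATIVES[display_id]
    placed = ledger.planted.setdefault(display_id, [])
    for k in range(count):
        names = tuple(f"M{display_id}N{len(placed)}_{v}" for v in range(3))
        for u, v in sorted(edges):
            if spec is not None and ref_pool is not None:
                net.add(_annotate(names[u], names[v], spec, rng, ledger, ref_pool))
            else:
                net.add(Interaction(tf=names[u], target=names[v], has_binding=True))
        placed.append(names)


def plant_motifs(
    net: RegulatoryNetwork,
    display_id: int,
    count: int,
    seed: int = 0,
) -> tuple[RegulatoryNetwork, GeneratorLedger]:
    """Add ``count`` vertex-disjoint instances of a triad class on fresh nodes.

    Returns a new network (the input is not mutated) and a ledger recording
    the planted node triples.  Planted edges carry bare binding evidence.
    """
    if display_id not in TRIAD_REPRESENTATIVES:
        raise ValueError(f"unknown triad display id {display_id}")
    rng = np.random.default_rng(seed)
    out = RegulatoryNetwork.from_interactions(net.interactions, label=net.label)
    ledger = GeneratorLedger()
    _plant(out, display_id, count, rng, None, ledger, None)
    return out, ledger


#: Hand-enumerated triad census of the ``census10`` fixture, committed with
#: it: chains ABD ACD BDE CDE GIJ HIJ, fan-ins BDF CDF, cycle DEF and
#: feed-forward loops ABC BCD GHI; every other node triple is disconnected.
CENSUS10_EXPECTED = {
    1: 6, 2: 0, 3: 2, 4: 0, 5: 0, 6: 1, 7: 3,
    8: 0, 9: 0, 10: 0, 11: 0, 12: 0, 13: 0,
}


def fixtures() -> dict[str, RegulatoryNetwork]:
    """Tiny fixed networks used throughout the test-suite.

    - ``ffl``: the single feed-forward loop (triad display id 7).
    - ``mutual_pair``: two cross-regulating TFs with a common target (id 10).
    - ``census10``: a 10-node network whose full triad census is committed as
      :data:`CENSUS10_EXPECTED`.
    - ``mini_venn``: 17 interactions with exactly 13 expression-only,
      3 binding-only and 1 doubly-supported (76.47 / 17.65 / 5.88 %).
    """

    def structural(edges: list[tuple[str, str]], label: str) -> RegulatoryNetwork:
        return RegulatoryNetwork.from_interactions(
            (Interaction(tf=u, target=v, has_binding=True) for u, v in edges),
            label=label,
        )

    ffl = structural([("X", "Y"), ("X", "Z"), ("Y", "Z")], "ffl")
    mutual = structural(
        [("X", "Y"), ("Y", "X"), ("X", "Z"), ("Y", "Z")], "mutual_pair"
    )
    census10 = structural(
        [
            ("A", "B"), ("A", "C"), ("B", "C"),  # FFL
            ("B", "D"), ("C", "D"),
            ("D", "E"), ("E", "F"), ("F", "D"),  # 3-cycle
            ("G", "H"), ("H", "I"), ("G", "I"),  # FFL
            ("I", "J"),
        ],
        "census10",
    )

    mini = RegulatoryNetwork(label="mini_venn")
    signs = [Sign.POSITIVE] * 7 + [Sign.NEGATIVE] * 4 + [Sign.DUAL, Sign.UNKNOWN]
    for k in range(13):
        mini.add(
            Interaction(
                tf=f"TF{k % 4}", target=f"E{k}",
                has_expression=True, sign=signs[k],
            )
        )
    for k in range(3):
        mini.add(Interaction(tf=f"TF{k}", target=f"B{k}", has_binding=True))
    mini.add(
        Interaction(
            tf="TF0", target="BOTH0",
            has_binding=True, has_expression=True, sign=Sign.POSITIVE,
        )
    )
    return {
        "ffl": ffl,
        "mutual_pair": mutual,
        "census10": census10,
        "mini_venn": mini,
    }
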