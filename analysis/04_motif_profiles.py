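#!/usr/bin/env python
"""Triad significance profiles of fixture and synthetic networks.

Profiles the small fixed networks and a planted-FFL benchmark against the
degree-preserving edge-switching ensemble, writing the SP table that a
plotting tool can render as the familiar 13-point profile curves.
"""

from pathlib import Path

from trnkit.motifs import TRIAD_LABELS, motif_profile, triad_census
from trnkit.synthetic import SyntheticSpec, fixtures, generate_trn

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 20260928
R = 500

fx = fixtures()
bench, _ = generate_trn(
    SyntheticSpec(
        n_tf=8, n_tg=40, in_degree_law=("geometric", 0.6),
        planted_motifs=((7, 30),), seed=SEED,
    )
)
nets = [fx["census10"], bench]
labels = ["census10", "planted_ffl_benchmark"]

for net, label in zip(nets, labels):
    census = triad_census(net)
    occupied = {i: c for i, c in census.counts.items() if c}
    print(f"{label}: {census.n_connected_triples} connected triads, census {occupied}")

profiles = motif_profile(nets, R=R, base_seed=SEED, labels=labels)
profiles.index.name = "network"
profiles.reset_index().to_csv(OUT / "04_motif_profiles.tsv", sep="\t", index=False)

sp7 = profiles.loc["planted_ffl_benchmark", "sp_7"]
print(
    f"\nensemble R={R}: the planted feed-forward loop "
    f"({TRIAD_LABELS[7]}, id 7) stands out with SP = {sp7:.3f} > 0, while the "
    "degree-preserving null absorbs the fan-in/fan-out structure"
)
print(f"profile table written to {OUT / '04_motif_profiles.tsv'}")
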