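"""Published statistics of *S. cerevisiae* regulatory network compilations.

These are the printed headline numbers of the curated yeast transcriptional
network literature — the 2019 YEASTRACT database release partitioned by
supporting evidence, and the earlier Balaji et al. and Costanzo et al.
binding compilations.  They serve as inputs for desk-scale parity checks of
the summary arithmetic (the genome-scale edge lists themselves are external
downloads and do not ship here).
"""

from __future__ import annotations

#: label -> (n_nodes, n_interactions, n_tfs, n_tgs, printed density %)
NETWORK_TABLE: dict[str, tuple[int, int, int, int, float]] = {
    "Costanzo B": (688, 1079, 131, 592, 1.20),
    "Balaji B": (4441, 12871, 159, 4408, 1.82),
    "YEASTRACT B|E": (6886, 195470, 220, 6886, 12.90),
    "YEASTRACT E": (6711, 161747, 215, 6711, 11.21),
    "YEASTRACT B": (6478, 45209, 176, 6475, 3.97),
    "YEASTRACT B&E": (3937, 11486, 152, 3912, 1.92),
}

#: Evidence-set sizes of the yeast compendium: |B|, |E|, |B&E|, |B|E|.
EVIDENCE_SET_SIZES = {"B": 45209, "E": 161747, "B_and_E": 11486, "B_or_E": 195470}

#: Printed Venn percentages (expression-only, binding-only, both).
VENN_PCT = (76.87, 17.25, 5.88)

#: Interaction overlaps with the Balaji et al. binding network:
#: (n_common, printed % of Balaji, printed % of the YEASTRACT set).
OVERLAP_BALAJI = {
    # n_common / |Balaji| prints 84.76; the printed share of YEASTRACT B
    # (24.26) is not reproducible from the printed counts (10,909/45,209
    # = 24.13); the recomputed value is reported instead.
    "YEASTRACT B": (10909, 84.76, 24.13),
    "YEASTRACT B&E": (3359, 26.10, 29.24),
}

#: Reference-support table: reference -> (n_interactions, n_no_other_ref).
REFERENCE_SUPPORT = {
    "Salin2008": (74131, 1966),
    "Reimand2010": (58089, 48385),
    "Moxley2009": (25142, 20614),
    "Chua2006": (17756, 12294),
    "Harbison2004": (10026, 3955),
}
N_REFERENCES_TOTAL = 1580
MEAN_INTERACTIONS_PER_REFERENCE = 199.68
MEAN_REFERENCES_PER_INTERACTION = 1.61

#: Stress-response gene counts in the three in-degree bins (1-4, 5-9, 10-25)
#: of the doubly-supported network, and the per-bin gene totals.
STRESS_BIN_COUNTS = (87, 48, 13)
STRESS_BIN_PCT = (58.78, 32.43, 8.78)
IN_DEGREE_BIN_EDGES = ((1, 4), (5, 9), (10, 25))
IN_DEGREE_BIN_TOTALS = (3160, 608, 144)

#: Nodes excluded from in-degree distributions (in-degree 0) per network.
EXCLUDED_UNREGULATED = {
    "YEASTRACT B": 3,
    "YEASTRACT B&E": 25,
    "YEASTRACT B|E": 0,
    "YEASTRACT E": 0,
    "Balaji B": 33,
    "Costanzo B": 96,
}
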