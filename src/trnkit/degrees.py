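"""In- and out-degree tables, distributions and TF rankings.

In a regulatory network the in-degree of a gene is the number of distinct TFs
controlling it and the out-degree of a TF the number of distinct genes it
controls.  Degrees count interaction partners, never publications or
conditions, and auto-regulation (a self-loop) contributes one to both degrees
of its node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .network import RegulatoryNetwork

__all__ = [
    "degree_table",
    "DegreeDistribution",
    "in_degree_distribution",
    "out_degree_distribution",
    "rank_tfs",
]


def degree_table(net: RegulatoryNetwork) -> pd.DataFrame:
    """Per-node in- and out-degrees, one row per node.

    Returns a DataFrame with columns ``node``, ``in_degree``, ``out_degree``
    sorted by node id; the handshake identity sum(in) = sum(out) = |E| holds
    by construction.
    """
    nodes = sorted(net.nodes)
    in_deg = dict.fromkeys(nodes, 0)
    out_deg = dict.fromkeys(nodes, 0)
    for tf, tg in net.pairs:
        out_deg[tf] += 1
        in_deg[tg] += 1
    return pd.DataFrame(
        {
            "node": nodes,
            "in_degree": [in_deg[n] for n in nodes],
            "out_degree": [out_deg[n] for n in nodes],
        }
    )


@dataclass
class DegreeDistribution:
    """Node counts per degree value (or per degree bin).

    ``counts`` maps a degree (``direction='in'``) or the inclusive lower edge
    of a half-open bin ``[k*w, (k+1)*w)`` (``direction='out'`` with
    ``bin_width=w``) to the number of nodes.
    """

    direction: str
    counts: dict[int, int]
    n_excluded: int = 0
    label: str = ""
    bin_width: int = 1

    def to_frame(self) -> pd.DataFrame:
        key = "degree" if self.bin_width == 1 else "bin_start"
        return pd.DataFrame(
            {key: list(self.counts), "n_nodes": list(self.counts.values())}
        )


def in_degree_distribution(
    table: pd.DataFrame, exclude_unregulated: bool = True
) -> DegreeDistribution:
    """Distribution of gene in-degrees.

    With ``exclude_unregulated`` (the published convention) nodes that no TF
    regulates (in-degree 0, i.e. pure TFs) are dropped and counted in
    ``n_excluded``.
    """
    degrees = table["in_degree"]
    excluded = 0
    if exclude_unregulated:
        excluded = int((degrees == 0).sum())
        degrees = degrees[degrees > 0]
    counts = degrees.value_counts().sort_index()
    return DegreeDistribution(
        direction="in",
        counts={int(k): int(v) for k, v in counts.items()},
        n_excluded=excluded,
    )


def out_degree_distribution(
    table: pd.DataFrame, bin_width: int = 200, truncate: int | None = None
) -> DegreeDistribution:
    """TF counts per out-degree range ``[k*w, (k+1)*w)``.

    Only TFs (out-degree ≥ 1) are counted.  ``truncate`` drops bins starting
    at or above the given degree (the published figure truncates at 2600).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    degrees = table.loc[table["out_degree"] >= 1, "out_degree"]
    bins = (degrees // bin_width) * bin_width
    counts = bins.value_counts().sort_index()
    out = {int(k): int(v) for k, v in counts.items()}
    if truncate is not None:
        out = {k: v for k, v in out.items() if k < truncate}
    return DegreeDistribution(
        direction="out", counts=out, bin_width=bin_width
    )


def rank_tfs(
    table: pd.DataFrame, k: int, end: str = "top"
) -> tuple[pd.DataFrame, int]:
    """The k TFs with highest (``end='top'``) or lowest (``end='bottom'``)
    out-degree, with tie inclusion.

    The k-th out-degree value becomes the reported threshold; every TF tied
    with it is included, so the returned table may hold more than k rows.
    Returns ``(records, threshold)`` with records sorted by out-degree
    (descending for top, ascending for bottom), ties broken by node id.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    tfs = table[table["out_degree"] >= 1]
    if len(tfs) < k:
        raise ValueError(f"table has only {len(tfs)} TFs, need at least {k}")
    ascending = end == "bottom"
    if end not in ("top", "bottom"):
        raise ValueError("end must be 'top' or 'bottom'")
    ordered = tfs.sort_values(
        ["out_degree", "node"], ascending=[ascending, True]
    ).reset_index(drop=True)
    threshold = int(ordered.loc[k - 1, "out_degree"])
    if ascending:
        selected = ordered[ordered["out_degree"] <= threshold]
    else:
        selected = ordered[ordered["out_degree"] >= threshold]
    return selected.reset_index(drop=True), threshold
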