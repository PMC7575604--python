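"""Functional-category analysis of regulated genes by in-degree bin.

Genes are assigned one major biological function (stress response, lipid
metabolism, multidrug resistance, ...).  To relate regulation intensity to
function, consecutive in-degrees whose functional composition is
statistically indistinguishable are merged into bins by chi-squared tests,
and the per-category distribution across the resulting bins is tabulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .network import pct

logger = logging.getLogger(__name__)

__all__ = [
    "load_annotations",
    "BinSpec",
    "chi_square_bin_merge",
    "CategoryDistribution",
    "category_distribution",
    "degree_category_contingency",
]


def load_annotations(path: str | Path) -> dict[str, str]:
    """Read a gene→functional-category TSV (columns ``gene``, ``category``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    dup = df["gene"].str.upper().duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate gene annotations: "
                         f"{sorted(df.loc[dup, 'gene'])[:5]}")
    return dict(zip(df["gene"].str.upper(), df["category"]))


@dataclass(frozen=True)
class BinSpec:
    """Ordered, contiguous, disjoint integer in-degree intervals covering
    [1, max observed].  ``edges[i] = (lo_i, hi_i)`` inclusive on both ends."""

    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("BinSpec needs at least one interval")
        if self.edges[0][0] != 1:
            raise ValueError("first interval must start at in-degree 1")
        for (lo, hi), (nlo, _) in zip(self.edges, self.edges[1:]):
            if hi < lo or nlo != hi + 1:
                raise ValueError(f"intervals must be contiguous and ordered: {self.edges}")
        if self.edges[-1][1] < self.edges[-1][0]:
            raise ValueError("empty final interval")

    def assign(self, degree: int) -> int:
        """Index of the bin containing ``degree``; raises if uncovered."""
        for i, (lo, hi) in enumerate(self.edges):
            if lo <= degree <= hi:
                return i
        raise ValueError(f"in-degree {degree} outside all bins {self.edges}")

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" if lo != hi else str(lo) for lo, hi in self.edges]


def degree_category_contingency(
    table: pd.DataFrame, annotations: dict[str, str]
) -> pd.DataFrame:
    """Per-in-degree functional-category counts for regulated genes.

    Rows indexed by in-degree (≥ 1, ascending), columns are categories.
    Unannotated regulated genes are reported via a log message and excluded.
    """
    regulated = table[table["in_degree"] >= 1]
    missing = [n for n in regulated["node"] if n not in annotations]
    if missing:
        logger.warning(
            "%d regulated gene(s) lack a functional annotation (e.g. %s)",
            len(missing), missing[:5],
        )
    annotated = regulated[regulated["node"].isin(annotations)]
    cats = annotated["node"].map(annotations)
    return pd.crosstab(annotated["in_degree"], cats).sort_index()


def chi_square_bin_merge(
    contingency: pd.DataFrame,
    alpha: float = 0.05,
    min_expected: float = 5.0,
) -> BinSpec:
    """Merge consecutive in-degrees into bins of homogeneous functional
    composition.

    Greedy left-to-right agglomeration: the accumulated bin is compared with
    the next in-degree's category counts by a chi-squared test on the 2×C
    contingency table (categories whose expected count falls below
    ``min_expected`` are pooled into an "other" column); the degree joins the
    bin while p > alpha, otherwise it starts a new bin.  A degree slice with
    zero total merges unconditionally with a warning.  Deterministic for
    fixed inputs.
    """
    if contingency.empty or len(contingency.index) < 1:
        raise ValueError("contingency table must have at least one in-degree row")
    if (contingency.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    degrees = [int(d) for d in contingency.index]
    if degrees != sorted(degrees):
        raise ValueError("contingency rows must be indexed by ascending in-degree")

    bins: list[tuple[int, int]] = []
    acc = contingency.iloc[0].to_numpy(dtype=float)
    start = degrees[0]
    prev = degrees[0]
    for i in range(1, len(degrees)):
        row = contingency.iloc[i].to_numpy(dtype=float)
        if _merge_p_value(acc, row, min_expected) > alpha:
            acc = acc + row
        else:
            bins.append((start, degrees[i] - 1))
            start = degrees[i]
            acc = row
        prev = degrees[i]
    bins.append((start, prev))
    # cover [1, max] even when low in-degrees are unobserved
    if bins[0][0] != 1:
        bins[0] = (1, bins[0][1])
    return BinSpec(edges=tuple(bins))


def _merge_p_value(acc: np.ndarray, row: np.ndarray, min_expected: float) -> float:
    """p-value of the homogeneity test between an accumulated bin and the
    next in-degree slice; returns 1.0 (merge) for degenerate tables."""
    if acc.sum() == 0 or row.sum() == 0:
        warnings.warn("degree slice with zero total merged unconditionally")
        return 1.0
    tab = np.vstack([acc, row])
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2:
        return 1.0
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    low = expected.min(axis=0) < min_expected
    if low.any() and (~low).sum() >= 1:
        pooled = tab[:, low].sum(axis=1, keepdims=True)
        tab = np.hstack([tab[:, ~low], pooled])
    if tab.shape[1] < 2:
        return 1.0
    _, p, _, _ = chi2_contingency(tab, correction=False)
    return float(p)


@dataclass
class CategoryDistribution:
    """Gene counts and within-category percentages per (category, bin)."""

    counts: pd.DataFrame  # categories × bins
    bin_labels: list[str]
    n_unannotated: int

    @property
    def percentages(self) -> pd.DataFrame:
        """Within-category percentages (each row sums to ~100)."""
        totals = self.counts.sum(axis=1)
        return self.counts.apply(
            lambda col: [pct(v, t) if t else 0.0 for v, t in zip(col, totals)]
        )

    @property
    def bin_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def category_distribution(
    table: pd.DataFrame,
    annotations: dict[str, str],
    bins: BinSpec,
) -> CategoryDistribution:
    """Cross-tabulate regulated genes by functional category and in-degree bin.

    Every regulated gene's in-degree must fall inside a bin; a gene outside
    all bins raises an error naming it.  Genes without an annotation are
    tallied separately, never silently dropped.
    """
    regulated = table[table["in_degree"] >= 1]
    labels = bins.labels()
    rows: dict[str, np.ndarray] = {}
    n_unannotated = 0
    for node, deg in zip(regulated["node"], regulated["in_degree"]):
        try:
            b = bins.assign(int(deg))
        except ValueError as exc:
            raise ValueError(f"gene {node}: {exc}") from exc
        cat = annotations.get(node)
        if cat is None:
            n_unannotated += 1
            continue
        rows.setdefault(cat, np.zeros(len(labels), dtype=int))[b] += 1
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    counts = counts.sort_index()
    return CategoryDistribution(
        counts=counts, bin_labels=labels, n_unannotated=n_unannotated
    )
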