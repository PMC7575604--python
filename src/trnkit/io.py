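"""Reading and writing annotated regulatory networks.

The native format is a UTF-8 TSV with a header row and columns ``tf``,
``target``, ``evidence`` (semicolon-separated tokens from {binding,
expression}), ``sign``, ``conditions`` and ``references`` (both
semicolon-separated).  Multiple rows per (tf, target) pair are permitted and
merge on read.  Published binding-only networks distributed as bare 2-column
edge lists are read with :func:`read_edge_list`.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping

from .network import Interaction, RegulatoryNetwork, Sign, normalize_gene

logger = logging.getLogger(__name__)

EVIDENCE_VOCABULARY = frozenset({"binding", "expression"})

DEFAULT_DIALECT: dict[str, str] = {
    "tf": "tf",
    "target": "target",
    "evidence": "evidence",
    "sign": "sign",
    "conditions": "conditions",
    "references": "references",
}

_COLUMNS = ("tf", "target", "evidence", "sign", "conditions", "references")


def _split(cell: str | None) -> list[str]:
    if not cell:
        return []
    return [tok.strip() for tok in cell.split(";") if tok.strip()]


def read_network(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    label: str | None = None,
) -> RegulatoryNetwork:
    """Read a network from the annotated TSV dialect.

    Duplicate (tf, target) rows merge: evidence flags OR, reference and
    condition sets union, per-row signs aggregate.  Rows whose evidence cell
    is empty carry no usable annotation and are dropped with a logged count.

    Raises ``ValueError`` naming the offending line for malformed rows and
    listing the accepted vocabulary for unknown evidence tokens.
    """
    path = Path(path)
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)

    net = RegulatoryNetwork(label=label if label is not None else path.stem)
    n_dropped = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file (missing header row)")
        for required in (colmap["tf"], colmap["target"], colmap["evidence"]):
            if required not in reader.fieldnames:
                raise ValueError(f"{path}: missing mandatory column {required!r}")
        for row in reader:
            lineno = reader.line_num
            tf = row.get(colmap["tf"]) or ""
            target = row.get(colmap["target"]) or ""
            if not tf.strip() or not target.strip():
                raise ValueError(f"{path}:{lineno}: malformed row (empty tf/target)")
            evidence = _split(row.get(colmap["evidence"]))
            if not evidence:
                n_dropped += 1
                continue
            unknown = set(evidence) - EVIDENCE_VOCABULARY
            if unknown:
                raise ValueError(
                    f"{path}:{lineno}: unknown evidence token(s) {sorted(unknown)}; "
                    f"accepted vocabulary: {sorted(EVIDENCE_VOCABULARY)}"
                )
            has_binding = "binding" in evidence
            has_expression = "expression" in evidence
            sign_cell = (row.get(colmap["sign"]) or "").strip()
            if has_expression:
                sign = Sign(sign_cell) if sign_cell else Sign.UNKNOWN
            else:
                sign = Sign.NOT_APPLICABLE
            net.add(
                Interaction(
                    tf=normalize_gene(tf),
                    target=normalize_gene(target),
                    has_binding=has_binding,
                    has_expression=has_expression,
                    sign=sign,
                    conditions=frozenset(_split(row.get(colmap["conditions"]))),
                    references=frozenset(_split(row.get(colmap["references"]))),
                )
            )
    if n_dropped:
        logger.warning(
            "%s: dropped %d row(s) lacking evidence annotation", path, n_dropped
        )
    return net


def read_edge_list(
    path: str | Path,
    evidence: str = "binding",
    label: str | None = None,
) -> RegulatoryNetwork:
    """Read a plain 2-column (tf, target) edge list.

    Every association receives the default evidence kind (binding for the
    published ChIP-era compilations).
    """
    path = Path(path)
    if evidence not in EVIDENCE_VOCABULARY:
        raise ValueError(
            f"unknown evidence {evidence!r}; accepted: {sorted(EVIDENCE_VOCABULARY)}"
        )
    net = RegulatoryNetwork(label=label if label is not None else path.stem)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            net.add(
                Interaction(
                    tf=normalize_gene(fields[0]),
                    target=normalize_gene(fields[1]),
                    has_binding=evidence == "binding",
                    has_expression=evidence == "expression",
                    sign=Sign.UNKNOWN if evidence == "expression" else Sign.NOT_APPLICABLE,
                )
            )
    return net


def write_network(net: RegulatoryNetwork, path: str | Path) -> Path:
    """Write a network in the TSV dialect, deterministically ordered.

    Rows are sorted by (tf, target); set-valued cells are semicolon-joined in
    lexicographic order, so identical networks always produce byte-identical
    files and ``read_network`` round-trips losslessly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for it in net.interactions:
            evidence = [
                tok
                for tok, flag in (
                    ("binding", it.has_binding),
                    ("expression", it.has_expression),
                )
                if flag
            ]
            writer.writerow(
                [
                    it.tf,
                    it.target,
                    ";".join(evidence),
                    "" if it.sign is Sign.NOT_APPLICABLE else it.sign.value,
                    ";".join(sorted(it.conditions)),
                    ";".join(sorted(it.references)),
                ]
            )
    return path
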