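"""End-to-end analysis pipeline producing a deterministic report bundle.

A :class:`PipelineConfig` (YAML or JSON) names the input networks and the
analysis options; :func:`run_pipeline` writes, per network, a summary row, an
evidence Venn report, degree tables and distributions, ranked-TF tables,
functional-bin tables (when an annotation map is supplied) and the triad
significance profile, plus a manifest keyed by the configuration hash.
Identical configurations produce byte-identical bundles: all seeds are
explicit, every table is emitted in sorted order, and no output embeds a
timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import degrees, functional, io, motifs, network

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class NetworkInput:
    path: str
    format: str = "tsv"  # "tsv" (annotated dialect) or "edgelist"
    label: str | None = None
    evidence: str = "binding"  # default evidence for edge lists


@dataclass
class PipelineConfig:
    networks: list[NetworkInput] = field(default_factory=list)
    annotations: str | None = None
    evidence_selector: str | None = None  # B | E | B_or_E | B_and_E
    condition: str | None = None
    exclude_unregulated: bool = True
    out_degree_bin_width: int = 200
    out_degree_truncate: int | None = None
    rank_k: int = 25
    chi2_alpha: float = 0.05
    chi2_min_expected: float = 5.0
    motifs_R: int = 1000
    motifs_swap_factor: float = 10.0
    motifs_seed: int = 0
    motifs_preserve_mutual: bool = False
    output_dir: str = "results/pipeline"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        nets = [NetworkInput(**n) for n in raw.pop("networks", [])]
        return cls(networks=nets, **raw)

    def validate(self) -> None:
        if not self.networks:
            raise ValueError("config names no input networks")
        for n in self.networks:
            if not Path(n.path).exists():
                raise ValueError(f"input network not found: {n.path}")
            if n.format not in ("tsv", "edgelist"):
                raise ValueError(f"unknown network format {n.format!r}")
        if self.annotations is not None and not Path(self.annotations).exists():
            raise ValueError(f"annotation table not found: {self.annotations}")
        if self.motifs_seed is None:
            raise ValueError("motifs_seed must be explicit")

    def canonical_json(self) -> str:
        # output_dir is a destination, not an analysis parameter: the same
        # analysis written to two places must hash (and byte-compare) equal
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return json.dumps(payload, sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def _load(entry: NetworkInput) -> network.RegulatoryNetwork:
    if entry.format == "edgelist":
        return io.read_edge_list(entry.path, evidence=entry.evidence, label=entry.label)
    return io.read_network(entry.path, label=entry.label)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("summary")
def _summary_report(net, outdir: Path, prefix: str) -> list[str]:
    import pandas as pd

    s = network.summarize(net)
    df = pd.DataFrame(
        [
            {
                "network": s.label,
                "n_nodes": s.n_nodes,
                "n_interactions": s.n_interactions,
                "n_tfs": s.n_tfs,
                "n_tgs": s.n_tgs,
                "density_pct": s.density_pct,
            }
        ]
    )
    _write_tsv(df, outdir / f"{prefix}.summary.tsv")
    return [f"{prefix}.summary.tsv"]


@_stage("venn")
def _venn_report(net, outdir: Path, prefix: str) -> list[str]:
    v = network.venn_partition(net)
    _write_json(
        {
            "n_expression_only": v.n_expression_only,
            "n_binding_only": v.n_binding_only,
            "n_both": v.n_both,
            "n_union": v.n_union,
            "pct_expression_only": v.pct_expression_only,
            "pct_binding_only": v.pct_binding_only,
            "pct_both": v.pct_both,
            "sign_tallies": {s.value: c for s, c in sorted(v.sign_tallies.items())},
        },
        outdir / f"{prefix}.venn.json",
    )
    return [f"{prefix}.venn.json"]


@_stage("degrees")
def _degree_reports(net, cfg: PipelineConfig, outdir: Path, prefix: str) -> list[str]:
    table = degrees.degree_table(net)
    files = [f"{prefix}.degree_table.tsv"]
    _write_tsv(table, outdir / files[0])

    ind = degrees.in_degree_distribution(table, cfg.exclude_unregulated)
    _write_tsv(ind.to_frame(), outdir / f"{prefix}.in_degree_dist.tsv")
    files.append(f"{prefix}.in_degree_dist.tsv")

    outd = degrees.out_degree_distribution(
        table, bin_width=cfg.out_degree_bin_width, truncate=cfg.out_degree_truncate
    )
    _write_tsv(outd.to_frame(), outdir / f"{prefix}.out_degree_dist.tsv")
    files.append(f"{prefix}.out_degree_dist.tsv")

    n_tfs = int((table["out_degree"] >= 1).sum())
    k = min(cfg.rank_k, n_tfs)
    for end in ("top", "bottom"):
        ranked, threshold = degrees.rank_tfs(table, k=k, end=end)
        ranked = ranked.assign(threshold=threshold)
        name = f"{prefix}.tfs_{end}{k}.tsv"
        _write_tsv(ranked, outdir / name)
        files.append(name)
    return files


@_stage("functions")
def _functional_reports(net, cfg: PipelineConfig, outdir: Path, prefix: str) -> list[str]:
    import pandas as pd

    annotations = functional.load_annotations(cfg.annotations)
    table = degrees.degree_table(net)
    contingency = functional.degree_category_contingency(table, annotations)
    if contingency.empty:
        logger.warning("%s: no annotated regulated genes; skipping bins", prefix)
        return []
    bins = functional.chi_square_bin_merge(
        contingency, alpha=cfg.chi2_alpha, min_expected=cfg.chi2_min_expected
    )
    dist = functional.category_distribution(table, annotations, bins)
    counts = dist.counts.reset_index(names="category")
    pcts = dist.percentages.reset_index(names="category")
    long = counts.melt(id_vars="category", var_name="bin", value_name="count").merge(
        pcts.melt(id_vars="category", var_name="bin", value_name="pct"),
        on=["category", "bin"],
    ).sort_values(["category", "bin"], kind="stable")
    name = f"{prefix}.functional_bins.tsv"
    _write_tsv(long, outdir / name)
    _write_json(
        {"bins": dist.bin_labels, "n_unannotated": dist.n_unannotated},
        outdir / f"{prefix}.binspec.json",
    )
    return [name, f"{prefix}.binspec.json"]


@_stage("motifs")
def _motif_reports(net, cfg: PipelineConfig, outdir: Path, prefix: str) -> list[str]:
    import pandas as pd

    real = motifs.triad_census(net)
    if real.n_connected_triples == 0:
        z = {i: 0.0 for i in range(1, 14)}
    else:
        ens = motifs.ensemble_stats(
            net,
            R=cfg.motifs_R,
            base_seed=cfg.motifs_seed,
            swap_factor=cfg.motifs_swap_factor,
            preserve_mutual=cfg.motifs_preserve_mutual,
        )
        z = motifs.zscores(real, ens)
    profile = motifs.significance_profile(z)
    df = pd.DataFrame(
        {
            "triad_id": list(range(1, 14)),
            "label": [motifs.TRIAD_LABELS[i] for i in range(1, 14)],
            "count": [real.counts[i] for i in range(1, 14)],
            "z": [profile.z[i] for i in range(1, 14)],
            "sp": [profile.sp[i] for i in range(1, 14)],
        }
    )
    name = f"{prefix}.motif_profile.tsv"
    _write_tsv(df, outdir / name)
    return [name]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every analysis stage for every configured network.

    Returns the output directory; raises :class:`PipelineError` naming the
    failing stage on any error.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []
    for entry in config.networks:
        net = _load(entry)
        if config.evidence_selector:
            net = network.filter_by_evidence(net, config.evidence_selector)
        if config.condition:
            net = network.filter_by_condition(net, config.condition)
        prefix = entry.label or Path(entry.path).stem
        if len(net) == 0:
            logger.warning("%s: empty after filtering; skipped", prefix)
            continue
        produced += _summary_report(net, outdir, prefix)
        produced += _venn_report(net, outdir, prefix)
        produced += _degree_reports(net, config, outdir, prefix)
        if config.annotations:
            produced += _functional_reports(net, config, outdir, prefix)
        produced += _motif_reports(net, config, outdir, prefix)
    manifest = {
        "config_sha256": config.sha256(),
        "motifs_seed": config.motifs_seed,
        "outputs": sorted(produced),
    }
    _write_json(manifest, outdir / "manifest.json")
    return outdir
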