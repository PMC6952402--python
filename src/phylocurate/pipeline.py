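"""End-to-end curation pipeline.

Stage order is fixed (order sensitivity is real — e.g. column deletion
changes overlap counts) and matches the published workflow: length and
occupancy cuts, deduplication and terminal-X trimming happen on the raw
members; alignment and ambiguous-region masking are accepted as upstream
external steps; then consensus-"change" filtering, island masking, sparse-
column deletion, the alignment-length cut and the overlap filter; then
tree-based paralog pruning, the post-prune occupancy and focal-taxon cuts,
and finally concatenation. The curation path contains no randomness:
rerunning on identical input is byte-identical.

Manual contamination screening (BLAST of conspicuous sequences against a
reference database) is out of scope; instead survivors with a "change"
value in (50, max_change] are flagged for human review in the manifest —
flagging only, nothing is removed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import alnfilters, seqfilters
from .errors import ConfigError, DataError
from .io import (
    DEFAULT_SCHEME,
    FilterReport,
    HeaderScheme,
    OGAlignment,
    read_og_fasta,
    write_manifest,
    write_report_tsv,
)
from .pruning import apply_prune, prune_to_single_copy
from .seqfilters import FilterThresholds
from .supermatrix import Supermatrix, concatenate, matrix_stats, write_supermatrix
from .trees import GeneTree, collapse_low_support, read_newick

#: Canonical stage order. "prune" runs only when trees are supplied,
#: "focal" only when a focal taxon is configured.
STAGE_ORDER = (
    "minlen",
    "mintaxa",
    "dedup",
    "xtrim",
    "change",
    "islands",
    "columns",
    "alnlen",
    "overlap",
    "prune",
    "mintaxa_post",
    "focal",
)

TREE_SUFFIXES = (".nwk", ".tre", ".tree", ".newick")
FASTA_SUFFIXES = (".fa", ".fasta", ".faa")


@dataclass
class PipelineConfig:
    input_dir: str | Path
    output_dir: str | Path
    trees_dir: str | Path | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    stages: tuple[str, ...] | None = None  # None = all applicable
    header_scheme: HeaderScheme = DEFAULT_SCHEME
    model: str = "AUTO"
    ends_count_as_flanks: bool = False
    cascade_islands: bool = False
    sort_ogs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = FilterThresholds(**raw.pop("thresholds", {}))
        scheme = HeaderScheme(**raw.pop("header_scheme", {}))
        stages = raw.pop("stages", None)
        if stages is not None:
            stages = tuple(stages)
        known = {
            "input_dir", "output_dir", "trees_dir", "model",
            "ends_count_as_flanks", "cascade_islands", "sort_ogs",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(thresholds=thr, header_scheme=scheme, stages=stages, **raw)


@dataclass
class CurationResult:
    ogs: list[OGAlignment]
    supermatrix: Supermatrix | None
    stage_reports: list[FilterReport]
    manifest: dict

    @property
    def report(self) -> FilterReport:
        return FilterReport.merge(self.stage_reports, "pipeline")


def _resolve_stages(
    requested: tuple[str, ...] | None,
    have_trees: bool,
    thresholds: FilterThresholds,
) -> list[str]:
    if requested is None:
        stages = [s for s in STAGE_ORDER]
        if not have_trees:
            stages.remove("prune")
        if not thresholds.focal_taxon:
            stages.remove("focal")
        return stages
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    if "prune" in requested and not have_trees:
        raise ConfigError("prune stage enabled but no trees supplied")
    if "focal" in requested and not thresholds.focal_taxon:
        raise ConfigError("focal stage enabled but focal_taxon unset")
    return [s for s in STAGE_ORDER if s in requested]


def _prune_og(
    og: OGAlignment,
    trees: Mapping[str, GeneTree],
    thresholds: FilterThresholds,
) -> tuple[OGAlignment, FilterReport]:
    taxa = [m.taxon_id for m in og.members]
    if len(taxa) == len(set(taxa)):
        # Single-copy already; the pruner would keep everything.
        return og, FilterReport("prune")
    if og.og_id not in trees:
        raise DataError(
            f"OG {og.og_id} has duplicated taxa but no gene tree was supplied"
        )
    collapsed = collapse_low_support(trees[og.og_id], thresholds.collapse_support)
    lengths = {m.label: m.nongap_count() for m in og.members}
    result = prune_to_single_copy(collapsed, lengths)
    return apply_prune(og, result)


def curate_dataset(
    ogs: Sequence[OGAlignment],
    thresholds: FilterThresholds | None = None,
    trees: Mapping[str, GeneTree] | None = None,
    stages: tuple[str, ...] | None = None,
    ends_count_as_flanks: bool = False,
    cascade_islands: bool = False,
    sort_ogs: bool = True,
) -> CurationResult:
    """Run the curation stages on in-memory OG alignments.

    Returns the surviving alignments, the concatenated supermatrix (``None``
    when nothing survives), per-stage reports, and a manifest with
    per-stage bookkeeping counts.
    """
    thr = thresholds or FilterThresholds()
    trees = trees or {}
    enabled = _resolve_stages(stages, bool(trees), thr)
    current = list(ogs)
    input_members = sum(len(og) for og in current)
    stage_reports: list[FilterReport] = []
    stage_counts: dict[str, dict[str, int]] = {}

    def per_sequence_stage(name, fn):
        nonlocal current
        reps = []
        out = []
        for og in current:
            new_og, rep = fn(og)
            reps.append(rep)
            out.append(new_og)
        current = out
        record(name, FilterReport.merge(reps, name))

    def record(name: str, rep: FilterReport, members_lost_with_ogs: int = 0):
        stage_reports.append(rep)
        stage_counts[name] = {
            "sequences_removed": len(rep.removed_sequences),
            "ogs_removed": len(rep.removed_ogs),
            "sequences_in_removed_ogs": members_lost_with_ogs,
            "segments_masked": len(rep.masked_segments),
            "columns_removed": len(rep.removed_columns),
        }

    def og_level_stage(name: str, keep_fn):
        """keep_fn(og) -> (keep: bool, reason: str)."""
        nonlocal current
        rep = FilterReport(name)
        lost = 0
        out = []
        for og in current:
            keep, reason = keep_fn(og)
            if keep:
                out.append(og)
            else:
                rep.removed_ogs.append((og.og_id, reason))
                lost += len(og)
        current = out
        record(name, rep, members_lost_with_ogs=lost)

    for stage in enabled:
        if stage == "minlen":
            per_sequence_stage(
                "min_length", lambda og: seqfilters.filter_min_length(og, thr.min_seq_len)
            )
        elif stage in ("mintaxa", "mintaxa_post"):
            name = "min_taxa" if stage == "mintaxa" else "min_taxa_post"
            min_taxa = thr.min_taxa
            og_level_stage(
                name,
                lambda og: (len(og.taxa()) >= min_taxa, "min_taxa"),
            )
        elif stage == "dedup":
            per_sequence_stage(
                "dedup", lambda og: seqfilters.dedup_identical(og, thr.dedup_within_taxon)
            )
        elif stage == "xtrim":
            def xtrim(og):
                rep = FilterReport("xtrim")
                members = []
                for m in og.members:
                    trimmed, segs = seqfilters.trim_terminal_x(m, thr.x_window)
                    for start, end in segs:
                        rep.masked_segments.append((og.og_id, m.seq_id, start, end))
                    members.append(trimmed)
                return og.replace_members(members), rep

            per_sequence_stage("xtrim", xtrim)
        elif stage == "change":
            per_sequence_stage(
                "change",
                lambda og: seqfilters.filter_by_change(
                    og, thr.max_change, thr.change_denominator
                ),
            )
        elif stage == "islands":
            per_sequence_stage(
                "islands",
                lambda og: alnfilters.remove_short_islands(
                    og,
                    ends_count_as_flanks=ends_count_as_flanks,
                    cascade=cascade_islands,
                ),
            )
        elif stage == "columns":
            def columns(og):
                new_og, rep, _cmap = alnfilters.filter_sparse_columns(
                    og, thr.min_nongap_col
                )
                return new_og, rep

            per_sequence_stage("columns", columns)
        elif stage == "alnlen":
            og_level_stage(
                "min_aln_len",
                lambda og: (og.length >= thr.min_aln_len, "min_aln_len"),
            )
        elif stage == "overlap":
            per_sequence_stage(
                "min_overlap",
                lambda og: seqfilters.filter_min_overlap(og, thr.min_overlap),
            )
        elif stage == "prune":
            per_sequence_stage("prune", lambda og: _prune_og(og, trees, thr))
        elif stage == "focal":
            focal = thr.focal_taxon
            og_level_stage(
                "focal",
                lambda og: (
                    any(m.taxon_id == focal for m in og.members),
                    "missing_focal",
                ),
            )

    # Review flags: conspicuous but surviving sequences (change in
    # (50, max_change]) a human may want to inspect; nothing is removed.
    review_flags = []
    for og in current:
        if not og.members:
            continue
        cons = seqfilters.consensus_sequence(og)
        for m in og.members:
            value = seqfilters.change_percent(m, cons, thr.change_denominator)
            if 50.0 < value <= thr.max_change:
                review_flags.append(
                    {"og_id": og.og_id, "taxon_id": m.taxon_id,
                     "seq_id": m.seq_id, "change": round(value, 4)}
                )

    surviving_members = sum(len(og) for og in current)
    removed_total = sum(
        c["sequences_removed"] + c["sequences_in_removed_ogs"]
        for c in stage_counts.values()
    )
    sm = None
    stats = None
    if current and any(og.members for og in current):
        sm = concatenate([og for og in current if og.members], sort_ogs=sort_ogs)
        stats = matrix_stats(sm)

    config_fingerprint = hashlib.sha256(
        json.dumps(
            {"thresholds": asdict(thr), "stages": enabled,
             "ends_count_as_flanks": ends_count_as_flanks,
             "cascade_islands": cascade_islands, "sort_ogs": sort_ogs},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]

    manifest = {
        "config_fingerprint": config_fingerprint,
        "thresholds": asdict(thr),
        "stages": enabled,
        "input": {"n_ogs": len(ogs), "n_sequences": input_members},
        "stage_counts": stage_counts,
        "output": {
            "n_ogs": len(current),
            "n_sequences": surviving_members,
        },
        "bookkeeping": {
            "input_sequences": input_members,
            "surviving_sequences": surviving_members,
            "removed_sequences_total": removed_total,
            "identity_holds": input_members == surviving_members + removed_total,
        },
        "review_flags": review_flags,
    }
    if stats is not None:
        manifest["matrix_stats"] = {
            "n_taxa": stats.n_taxa,
            "n_genes": stats.n_genes,
            "total_length": stats.total_length,
            "pct_missing": stats.pct_missing,
        }
    return CurationResult(
        ogs=current, supermatrix=sm, stage_reports=stage_reports, manifest=manifest
    )


def load_input_ogs(
    input_dir: str | Path, scheme: HeaderScheme = DEFAULT_SCHEME
) -> list[OGAlignment]:
    input_dir = Path(input_dir)
    paths = sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in FASTA_SUFFIXES
    )
    if not paths:
        raise DataError(f"no FASTA files ({'/'.join(FASTA_SUFFIXES)}) in {input_dir}")
    return [read_og_fasta(p, scheme) for p in paths]


def load_trees(trees_dir: str | Path) -> dict[str, GeneTree]:
    trees_dir = Path(trees_dir)
    trees = {}
    for p in sorted(trees_dir.iterdir()):
        if p.suffix.lower() in TREE_SUFFIXES:
            trees[p.stem] = read_newick(p)
    return trees


def run_pipeline(config: PipelineConfig) -> CurationResult:
    """File-level entry point: read OGs (and trees), curate, write outputs.

    Writes into ``config.output_dir``: the supermatrix FASTA + partition
    file + stats JSON + occupancy TSV (when anything survives), the
    cumulative filter report TSV, and the run manifest JSON.
    """
    ogs = load_input_ogs(config.input_dir, config.header_scheme)
    trees = load_trees(config.trees_dir) if config.trees_dir else {}
    result = curate_dataset(
        ogs,
        thresholds=config.thresholds,
        trees=trees,
        stages=config.stages,
        ends_count_as_flanks=config.ends_count_as_flanks,
        cascade_islands=config.cascade_islands,
        sort_ogs=config.sort_ogs,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if result.supermatrix is not None:
        write_supermatrix(result.supermatrix, out / "supermatrix", model=config.model)
    write_report_tsv(result.stage_reports, out / "filter_report.tsv")
    write_manifest(result.manifest, out / "manifest.json")
    return result


def summarize_run(manifest: dict) -> str:
    """Human-readable per-stage summary built from the manifest alone."""
    if "stage_counts" not in manifest or "input" not in manifest:
        raise DataError("manifest lacks stage_counts/input sections")
    lines = ["stage             seqs_removed  ogs_removed  segments  columns"]
    for stage in manifest["stages"]:
        name = {
            "minlen": "min_length", "mintaxa": "min_taxa",
            "mintaxa_post": "min_taxa_post", "alnlen": "min_aln_len",
            "overlap": "min_overlap",
        }.get(stage, stage)
        c = manifest["stage_counts"].get(name)
        if c is None:
            continue
        lines.append(
            f"{name:<17} {c['sequences_removed'] + c['sequences_in_removed_ogs']:>12}"
            f" {c['ogs_removed']:>12} {c['segments_masked']:>9}"
            f" {c['columns_removed']:>8}"
        )
    ms = manifest.get("matrix_stats")
    if ms:
        lines.append(
            f"final matrix: {ms['n_genes']} genes totalling "
            f"{ms['total_length']} amino acids, {ms['n_taxa']} taxa, "
            f"{ms['pct_missing']:.2f}% missing data"
        )
    else:
        lines.append("final matrix: empty (nothing survived curation)")
    return "\n".join(lines)
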