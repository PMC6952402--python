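"""Alignment- and OG-level filters.

Covers deletion of short "islands" (likely mistranslated regions: short
residue runs in one row stranded between long gap runs), removal of sparsely
occupied columns, the minimum-alignment-length cut, the minimum-taxon-
occupancy cut, and the required-focal-taxon rule.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError
from .io import GAP, FilterReport, OGAlignment


def _islands(residues: str) -> list[tuple[int, int]]:
    """Maximal non-gap runs as 0-based half-open (start, end) spans."""
    spans = []
    start = None
    for i, c in enumerate(residues):
        if c != GAP and start is None:
            start = i
        elif c == GAP and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(residues)))
    return spans


def _mask_row_islands(
    residues: str, max_island: int, min_flank: int, ends_count_as_flanks: bool
) -> tuple[str, list[tuple[int, int]]]:
    spans = _islands(residues)
    masked: list[tuple[int, int]] = []
    chars = list(residues)
    for idx, (start, end) in enumerate(spans):
        if end - start > max_island:
            continue
        left_gap = start - (spans[idx - 1][1] if idx > 0 else 0)
        right_gap = (spans[idx + 1][0] if idx + 1 < len(spans) else len(residues)) - end
        # A flank is a run of >= min_flank consecutive gaps, wherever it
        # sits. The bare alignment end is not a flank, so an island sitting
        # directly at the end (zero-gap flank) is never deleted — unless
        # ends_count_as_flanks lets the boundary itself play the flank role.
        if ends_count_as_flanks:
            left_ok = (start - left_gap) == 0 or left_gap >= min_flank
            right_ok = (end + right_gap) == len(residues) or right_gap >= min_flank
        else:
            left_ok = left_gap >= min_flank
            right_ok = right_gap >= min_flank
        if left_ok and right_ok:
            for i in range(start, end):
                chars[i] = GAP
            masked.append((start, end))
    return "".join(chars), masked


def remove_short_islands(
    aln: OGAlignment,
    max_island: int = 20,
    min_flank: int = 10,
    ends_count_as_flanks: bool = False,
    cascade: bool = False,
) -> tuple[OGAlignment, FilterReport]:
    """Mask likely mistranslated islands: runs of at most ``max_island``
    residues with at least ``min_flank`` consecutive gaps on both sides.

    Alignment ends do not count as gap flanks by default, so a terminal
    fragment is never deleted here (terminal junk is the terminal-X rule's
    job); ``ends_count_as_flanks`` flips that for sensitivity analysis.
    Evaluation is a single pass over the input row — gaps created by masking
    one island do not qualify a neighbour — unless ``cascade`` requests
    fixpoint iteration.
    """
    report = FilterReport("islands")
    kept = []
    for m in aln.members:
        residues, masked = _mask_row_islands(
            m.residues, max_island, min_flank, ends_count_as_flanks
        )
        if cascade:
            while masked:
                new_residues, more = _mask_row_islands(
                    residues, max_island, min_flank, ends_count_as_flanks
                )
                if not more:
                    break
                for seg in more:
                    report.masked_segments.append((aln.og_id, m.seq_id, *seg))
                residues = new_residues
        for seg in masked:
            report.masked_segments.append((aln.og_id, m.seq_id, *seg))
        kept.append(m.with_residues(residues) if residues != m.residues else m)
    return aln.replace_members(kept), report


def filter_sparse_columns(
    aln: OGAlignment, min_nongap_col: int = 4
) -> tuple[OGAlignment, FilterReport, list[int | None]]:
    """Delete columns with fewer than ``min_nongap_col`` residues.

    ``X`` counts as a residue. Returns the filtered alignment, the report,
    and a map old column index -> new index (``None`` for deleted columns)
    for coordinate bookkeeping.
    """
    report = FilterReport("columns")
    if not aln.members or aln.length == 0:
        return aln, report, [None] * aln.length if aln.length else []
    mat = aln.to_matrix()
    nongap = (mat != GAP.encode()).sum(axis=0)
    keep_mask = nongap >= min_nongap_col
    column_map: list[int | None] = []
    new_idx = 0
    for old, keep in enumerate(keep_mask):
        if keep:
            column_map.append(new_idx)
            new_idx += 1
        else:
            column_map.append(None)
            report.removed_columns.append((aln.og_id, old))
    if keep_mask.all():
        return aln, report, column_map
    sub = mat[:, keep_mask]
    members = [
        m.with_residues(sub[i].tobytes().decode("ascii"))
        for i, m in enumerate(aln.members)
    ]
    return aln.replace_members(members), report, column_map


def filter_min_aln_length(
    aln: OGAlignment, min_aln_len: int = 50
) -> tuple[bool, FilterReport]:
    """Keep/discard decision: discard alignments shorter than ``min_aln_len``
    columns (strict)."""
    report = FilterReport("min_aln_len")
    keep = aln.length >= min_aln_len
    if not keep:
        report.removed_ogs.append((aln.og_id, "min_aln_len"))
    return keep, report


def filter_min_taxa(
    ogs: Iterable[OGAlignment], min_taxa: int = 35
) -> tuple[list[OGAlignment], FilterReport]:
    """Discard OGs sampled for fewer than ``min_taxa`` DISTINCT taxa."""
    report = FilterReport("min_taxa")
    kept = []
    for og in ogs:
        if len(og.taxa()) < min_taxa:
            report.removed_ogs.append((og.og_id, "min_taxa"))
        else:
            kept.append(og)
    return kept, report


def require_taxon(
    ogs: Iterable[OGAlignment], focal_taxon: str | None
) -> tuple[list[OGAlignment], FilterReport]:
    """Discard OGs lacking a sequence from the focal taxon."""
    if not focal_taxon:
        raise ConfigError("require_taxon stage enabled but focal_taxon unset")
    report = FilterReport("focal")
    kept = []
    for og in ogs:
        if any(m.taxon_id == focal_taxon for m in og.members):
            kept.append(og)
        else:
            report.removed_ogs.append((og.og_id, "missing_focal"))
    return kept, report
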