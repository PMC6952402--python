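"""Per-sequence quality filters.

These implement the sequence-level curation rules applied to each
orthologous-group alignment: minimum ungapped length, removal of redundant
identical sequences, trimming of terminal ambiguity (``X``) runs,
consensus-divergence ("change") filtering of putative contaminants, and the
iterative minimum-overlap filter.

All thresholds are strict in the direction the rules state: a sequence of
exactly ``min_seq_len`` residues survives ("shorter than" deletes), a change
value of exactly ``max_change`` survives ("greater than" deletes), and an
overlap of exactly ``min_overlap`` columns satisfies "at least".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentShapeError, EmptyInputError
from .io import GAP, AlignedSequence, FilterReport, OGAlignment

# Alphabetical order of the consensus-eligible characters; argmax over this
# axis gives the alphabetical tie-break for free.
_CONSENSUS_CHARS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWXY", dtype="S1")


@dataclass
class FilterThresholds:
    """All numeric cut-offs of the curation pipeline.

    Defaults are the published values: sequences shorter than 100 residues
    deleted; terminal-X window of 20 residues; consensus-"change" above 75%
    deleted; pairwise overlap of at least 20 columns required; columns with
    fewer than 4 residues deleted; alignments shorter than 50 columns
    discarded; OGs with fewer than 35 distinct taxa discarded; gene-tree
    nodes with support below 50 collapsed.
    """

    min_seq_len: int = 100
    x_window: int = 20
    max_change: float = 75.0
    min_overlap: int = 20
    min_nongap_col: int = 4
    min_aln_len: int = 50
    min_taxa: int = 35
    collapse_support: float = 50.0
    focal_taxon: str | None = None
    dedup_within_taxon: bool = True
    change_denominator: str = "seq"  # or "alignment"

    def __post_init__(self) -> None:
        for name in (
            "min_seq_len",
            "x_window",
            "min_overlap",
            "min_nongap_col",
            "min_aln_len",
            "min_taxa",
            "collapse_support",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.max_change <= 100:
            raise ValueError("max_change must be in [0, 100]")
        if self.change_denominator not in ("seq", "alignment"):
            raise ValueError("change_denominator must be 'seq' or 'alignment'")


def filter_min_length(
    aln: OGAlignment, min_seq_len: int = 100
) -> tuple[OGAlignment, FilterReport]:
    """Delete members with fewer than ``min_seq_len`` non-gap residues.

    ``X`` counts as a residue (unknown identity is still occupancy).
    """
    report = FilterReport("min_length")
    kept = []
    for m in aln.members:
        if m.nongap_count() < min_seq_len:
            report.removed_sequences.append(
                (aln.og_id, m.taxon_id, m.seq_id, "min_length")
            )
        else:
            kept.append(m)
    return aln.replace_members(kept), report


def dedup_identical(
    aln: OGAlignment, within_taxon: bool = True
) -> tuple[OGAlignment, FilterReport]:
    """Remove redundant identical sequences, keeping the first in input order.

    Identity is judged on the gap-stripped residue string. By default only
    members of the same taxon are compared — identical sequences in
    different taxa may be genuine conservation and are kept; set
    ``within_taxon=False`` for global deduplication.
    """
    report = FilterReport("dedup")
    seen: dict[tuple, str] = {}
    kept = []
    for m in aln.members:
        stripped = m.residues.replace(GAP, "")
        key = (m.taxon_id if within_taxon else None, stripped)
        if key in seen:
            report.removed_sequences.append(
                (aln.og_id, m.taxon_id, m.seq_id, f"duplicate_of:{seen[key]}")
            )
        else:
            seen[key] = m.seq_id
            kept.append(m)
    return aln.replace_members(kept), report


def _trim_terminal_x_pass(
    residues: str, x_window: int
) -> tuple[str, list[tuple[int, int]]]:
    residue_cols = [i for i, c in enumerate(residues) if c != GAP]
    n = len(residue_cols)
    if n == 0:
        return residues, []
    mask_res: set[int] = set()
    segments: list[tuple[int, int]] = []

    front = [k for k in range(min(x_window, n)) if residues[residue_cols[k]] == "X"]
    if front:
        inner = max(front)
        mask_res.update(range(inner + 1))
        segments.append((residue_cols[0], residue_cols[inner] + 1))

    back = [
        k for k in range(max(0, n - x_window), n) if residues[residue_cols[k]] == "X"
    ]
    if back:
        inner = min(back)
        mask_res.update(range(inner, n))
        segments.append((residue_cols[inner], residue_cols[-1] + 1))

    if not mask_res:
        return residues, []
    out = list(residues)
    for k in mask_res:
        out[residue_cols[k]] = GAP
    return "".join(out), segments


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def trim_terminal_x(
    seq: AlignedSequence, x_window: int = 20
) -> tuple[AlignedSequence, list[tuple[int, int]]]:
    """Mask terminal low-quality runs flagged by an ``X`` near either end.

    The window is counted over the sequence's residues (gaps are skipped).
    If any ``X`` lies among the first ``x_window`` residues, everything from
    the sequence start through the innermost such ``X`` (inclusive) becomes
    missing data (``-``); symmetrically at the other end. Masking shortens
    the sequence, which can pull a further-out ``X`` into the terminal
    window, so the rule is applied to its fixpoint — the result never has
    an ``X`` among its terminal ``x_window`` residues, and the operation is
    idempotent. Alignment length is unchanged. Returns the trimmed sequence
    and the merged masked alignment-column spans (0-based half-open).
    """
    residues = seq.residues
    all_segments: list[tuple[int, int]] = []
    while True:
        residues, segments = _trim_terminal_x_pass(residues, x_window)
        if not segments:
            break
        all_segments.extend(segments)
    if not all_segments:
        return seq, []
    return seq.with_residues(residues), _merge_spans(all_segments)


def consensus_sequence(aln: OGAlignment) -> str:
    """Per-column plurality consensus over non-gap characters.

    ``X`` is eligible; a column with no residues yields ``-``; ties break
    alphabetically (fixed, documented — the choice is arbitrary but must be
    deterministic).
    """
    if not aln.members:
        raise EmptyInputError(f"OG {aln.og_id}: cannot take consensus of empty alignment")
    mat = aln.to_matrix()
    counts = (mat[None, :, :] == _CONSENSUS_CHARS[:, None, None]).sum(axis=1)
    best = np.argmax(counts, axis=0)
    cons = _CONSENSUS_CHARS[best]
    cons[counts.max(axis=0) == 0] = GAP.encode()
    return cons.tobytes().decode("ascii")


def change_percent(
    seq: AlignedSequence, consensus: str, denominator: str = "seq"
) -> float:
    """Percent of a sequence's positions differing from the consensus.

    With the default ``denominator='seq'`` both the mismatch count and the
    denominator range over the sequence's non-gap positions only, so a
    partial sequence is not penalised for columns where it has no data;
    ``denominator='alignment'`` divides by the full alignment length
    instead. An all-gap sequence scores 0.
    """
    if len(seq.residues) != len(consensus):
        raise AlignmentShapeError(
            f"{seq.label}: length {len(seq.residues)} vs consensus {len(consensus)}"
        )
    nongap = 0
    mismatch = 0
    for c, k in zip(seq.residues, consensus):
        if c == GAP:
            continue
        nongap += 1
        if c != k:
            mismatch += 1
    denom = nongap if denominator == "seq" else len(consensus)
    if denom == 0:
        return 0.0
    return 100.0 * mismatch / denom


def filter_by_change(
    aln: OGAlignment, max_change: float = 75.0, denominator: str = "seq"
) -> tuple[OGAlignment, FilterReport]:
    """Delete members whose consensus-"change" value exceeds ``max_change``.

    The consensus is computed once from the input alignment (single pass —
    not recomputed between removals), and the inequality is strict: a value
    exactly at the threshold survives.
    """
    report = FilterReport("change")
    if not aln.members:
        return aln, report
    cons = consensus_sequence(aln)
    kept = []
    for m in aln.members:
        value = change_percent(m, cons, denominator)
        if value > max_change:
            report.removed_sequences.append(
                (aln.og_id, m.taxon_id, m.seq_id, f"change:{value:.4f}")
            )
        else:
            kept.append(m)
    return aln.replace_members(kept), report


def filter_min_overlap(
    aln: OGAlignment, min_overlap: int = 20
) -> tuple[OGAlignment, FilterReport]:
    """Iteratively delete members that fail the pairwise-overlap requirement.

    Overlap(a, b) = number of columns where both rows have residues. While
    any member overlaps some other member by fewer than ``min_overlap``
    columns, the failing member with the fewest residues is deleted (tie:
    latest in input order) and overlaps are recomputed. Alignments with at
    most one member are returned unchanged (no pair exists to test).
    """
    report = FilterReport("min_overlap")
    if len(aln.members) <= 1:
        return aln, report
    present = aln.to_matrix() != GAP.encode()
    overlap = present.astype(np.int64) @ present.astype(np.int64).T
    nongap = present.sum(axis=1)
    alive = list(range(len(aln.members)))
    while len(alive) > 1:
        sub = overlap[np.ix_(alive, alive)]
        np.fill_diagonal(sub, np.iinfo(np.int64).max)
        min_per_member = sub.min(axis=1)
        failing = [alive[k] for k in range(len(alive)) if min_per_member[k] < min_overlap]
        if not failing:
            break
        victim = min(failing, key=lambda i: (nongap[i], -i))
        alive.remove(victim)
        m = aln.members[victim]
        report.removed_sequences.append(
            (aln.og_id, m.taxon_id, m.seq_id, "min_overlap")
        )
    kept = [aln.members[i] for i in alive]
    return aln.replace_members(kept), report
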