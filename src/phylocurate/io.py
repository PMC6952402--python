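"""Domain types and file I/O for orthologous-group (OG) alignments.

The pipeline's unit of work is one aligned amino-acid FASTA file per OG.
Headers encode a taxon identifier and a sequence identifier, by default as
``taxon|seqid`` split at the first ``|``. Residues are stored uppercase over
the 20 amino-acid letters plus ``X`` (ambiguous residue — deliberately NOT a
gap: several filters must see it as data) and ``-`` (gap / missing). ``?``
and ``.`` on input are normalised to ``-``.

Coordinate conventions: alignment columns are 0-based internally; masked
segments are 0-based half-open ``[start, end)``. The RAxML partition writer
is the one place 1-based inclusive coordinates appear, because that is the
dialect RAxML reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentShapeError,
    ConsistencyError,
    EmptyInputError,
    HeaderError,
)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALLOWED = frozenset(AA_LETTERS + "X" + GAP)

_NORMALISE = str.maketrans({"?": GAP, ".": GAP})


@dataclass(frozen=True)
class HeaderScheme:
    """How FASTA headers / tree leaf labels map to (taxon_id, seq_id).

    ``delimiter`` splits at its first occurrence; with ``taxon_only`` the
    whole header is the taxon id and seq_id is empty (single-sequence-per-
    taxon datasets).
    """

    delimiter: str = "|"
    taxon_only: bool = False

    def parse(self, header: str) -> tuple[str, str]:
        header = header.strip()
        if not header:
            raise HeaderError("empty FASTA header")
        if self.taxon_only:
            return header, ""
        if self.delimiter not in header:
            raise HeaderError(
                f"header {header!r} lacks delimiter {self.delimiter!r} "
                "(expected taxon{0}seqid)".format(self.delimiter)
            )
        taxon, seq_id = header.split(self.delimiter, 1)
        if not taxon:
            raise HeaderError(f"header {header!r} has empty taxon id")
        return taxon, seq_id

    def format(self, taxon_id: str, seq_id: str) -> str:
        if self.taxon_only or not seq_id:
            return taxon_id
        return f"{taxon_id}{self.delimiter}{seq_id}"


DEFAULT_SCHEME = HeaderScheme()


@dataclass(frozen=True)
class AlignedSequence:
    """One taxon's residue row in an OG alignment."""

    taxon_id: str
    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise HeaderError("taxon_id must be non-empty")
        if "|" in self.taxon_id:
            raise HeaderError(f"taxon_id {self.taxon_id!r} contains '|'")
        norm = self.residues.upper().translate(_NORMALISE)
        bad = set(norm) - ALLOWED
        if bad:
            raise AlignmentShapeError(
                f"{self.label}: illegal residue characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", norm)

    @property
    def label(self) -> str:
        """Tree-leaf style label ``taxon|seqid``."""
        return f"{self.taxon_id}|{self.seq_id}" if self.seq_id else self.taxon_id

    def nongap_count(self) -> int:
        """Number of residue characters; ``X`` counts, ``-`` does not."""
        return len(self.residues) - self.residues.count(GAP)

    def with_residues(self, residues: str) -> "AlignedSequence":
        return AlignedSequence(self.taxon_id, self.seq_id, residues)


class OGAlignment:
    """Rectangular alignment of one orthologous group.

    Member order is preserved from input — several filters break ties by
    input position, so order is part of the contract.
    """

    def __init__(self, og_id: str, members: Sequence[AlignedSequence]):
        members = list(members)
        if members:
            length = len(members[0].residues)
            for m in members:
                if len(m.residues) != length:
                    raise AlignmentShapeError(
                        f"OG {og_id}: member {m.label} has length "
                        f"{len(m.residues)}, expected {length}"
                    )
        else:
            length = 0
        self.og_id = og_id
        self.members = members
        self.length = length

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.members)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, OGAlignment)
            and self.og_id == other.og_id
            and self.members == other.members
        )

    def __repr__(self) -> str:
        return f"OGAlignment({self.og_id!r}, {len(self)} x {self.length})"

    def taxa(self) -> list[str]:
        """Distinct taxon ids, in order of first appearance."""
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.taxon_id, None)
        return list(seen)

    def replace_members(self, members: Sequence[AlignedSequence]) -> "OGAlignment":
        return OGAlignment(self.og_id, members)

    def to_matrix(self) -> np.ndarray:
        """(n_members, length) array of single-byte characters."""
        if not self.members:
            return np.empty((0, self.length), dtype="S1")
        return np.frombuffer(
            "".join(m.residues for m in self.members).encode("ascii"), dtype="S1"
        ).reshape(len(self.members), self.length)


@dataclass
class FilterReport:
    """Removal/masking record of one pipeline stage.

    ``removed_sequences``: (og_id, taxon_id, seq_id, reason).
    ``removed_columns``: (og_id, column_index) — indices in the stage's
    INPUT coordinates, 0-based.
    ``masked_segments``: (og_id, seq_id, start, end) — 0-based half-open
    alignment-column spans replaced by gaps.
    ``removed_ogs``: (og_id, reason) — the whole OG left the pipeline.
    """

    stage_name: str
    removed_sequences: list[tuple[str, str, str, str]] = field(default_factory=list)
    removed_columns: list[tuple[str, int]] = field(default_factory=list)
    masked_segments: list[tuple[str, str, int, int]] = field(default_factory=list)
    removed_ogs: list[tuple[str, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.removed_sequences
            or self.removed_columns
            or self.masked_segments
            or self.removed_ogs
        )

    @classmethod
    def merge(
        cls, reports: Iterable["FilterReport"], stage_name: str = "combined"
    ) -> "FilterReport":
        out = cls(stage_name)
        for r in reports:
            out.removed_sequences.extend(r.removed_sequences)
            out.removed_columns.extend(r.removed_columns)
            out.masked_segments.extend(r.masked_segments)
            out.removed_ogs.extend(r.removed_ogs)
        return out

    def write_tsv(self, path: str | Path) -> None:
        """Tab-separated dump, one event per line, ``event`` column first."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("event\tstage\tog_id\ttaxon_id\tseq_id\tstart\tend\treason\n")
            for og, tax, sid, reason in self.removed_sequences:
                fh.write(f"sequence\t{self.stage_name}\t{og}\t{tax}\t{sid}\t\t\t{reason}\n")
            for og, col in self.removed_columns:
                fh.write(f"column\t{self.stage_name}\t{og}\t\t\t{col}\t{col + 1}\t\n")
            for og, sid, start, end in self.masked_segments:
                fh.write(f"segment\t{self.stage_name}\t{og}\t\t{sid}\t{start}\t{end}\t\n")
            for og, reason in self.removed_ogs:
                fh.write(f"og\t{self.stage_name}\t{og}\t\t\t\t\t{reason}\n")


def read_og_fasta(
    path: str | Path,
    scheme: HeaderScheme = DEFAULT_SCHEME,
    og_id: str | None = None,
) -> OGAlignment:
    """Read one aligned FASTA file into an :class:`OGAlignment`.

    ``og_id`` defaults to the file stem. Raises :class:`EmptyInputError` for
    a record-less file, :class:`AlignmentShapeError` for ragged rows (the
    error names the offending record), :class:`HeaderError` for headers the
    scheme cannot parse.
    """
    path = Path(path)
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon, seq_id = scheme.parse(rec.description)
        members.append(AlignedSequence(taxon, seq_id, str(rec.seq)))
    if not members:
        raise EmptyInputError(f"{path}: no FASTA records")
    return OGAlignment(og_id if og_id is not None else path.stem, members)


def write_og_fasta(
    aln: OGAlignment,
    path: str | Path,
    scheme: HeaderScheme = DEFAULT_SCHEME,
    line_width: int = 60,
) -> None:
    """Write an alignment as FASTA, one record per member, fixed line width."""
    records = [
        SeqRecord(Seq(m.residues), id=scheme.format(m.taxon_id, m.seq_id), description="")
        for m in aln.members
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


def write_report_tsv(reports: Sequence[FilterReport], path: str | Path) -> None:
    """Concatenated per-stage TSV report (stages keep their own names)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("event\tstage\tog_id\ttaxon_id\tseq_id\tstart\tend\treason\n")
        for rep in reports:
            for og, tax, sid, reason in rep.removed_sequences:
                fh.write(f"sequence\t{rep.stage_name}\t{og}\t{tax}\t{sid}\t\t\t{reason}\n")
            for og, col in rep.removed_columns:
                fh.write(f"column\t{rep.stage_name}\t{og}\t\t\t{col}\t{col + 1}\t\n")
            for og, sid, start, end in rep.masked_segments:
                fh.write(f"segment\t{rep.stage_name}\t{og}\t\t{sid}\t{start}\t{end}\t\n")
            for og, reason in rep.removed_ogs:
                fh.write(f"og\t{rep.stage_name}\t{og}\t\t\t\t\t{reason}\n")


def write_partition_file(sm, path: str | Path, model: str = "AUTO") -> None:
    """RAxML-style partition file: ``MODEL, og_id = start-end`` per gene.

    Coordinates are 1-based inclusive, in concatenation order. Raises
    :class:`ConsistencyError` if the partitions do not tile
    ``[1, total_length]`` contiguously.
    """
    if not sm.partitions:
        raise ConsistencyError("supermatrix has no partitions")
    expected_start = 1
    for og_id, start, end in sm.partitions:
        if start != expected_start or end < start:
            raise ConsistencyError(
                f"partition {og_id} spans {start}-{end}; expected start "
                f"{expected_start} (partitions must tile without gaps/overlap)"
            )
        expected_start = end + 1
    if expected_start != sm.length + 1:
        raise ConsistencyError(
            f"partitions end at {expected_start - 1}, matrix length {sm.length}"
        )
    with Path(path).open("w") as fh:
        for og_id, start, end in sm.partitions:
            fh.write(f"{model}, {og_id} = {start}-{end}\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
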