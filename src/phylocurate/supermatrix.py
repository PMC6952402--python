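"""Partitioned concatenation and matrix occupancy statistics."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataError, EmptyInputError
from .io import GAP, write_partition_file


@dataclass
class MatrixStats:
    n_taxa: int
    n_genes: int
    total_length: int
    pct_missing: float
    per_taxon_occupancy: dict[str, float]
    per_gene_taxon_count: dict[str, int]


class Supermatrix:
    """Concatenated alignment: taxa as rows, genes as column blocks.

    ``partitions`` holds (og_id, start, end) with 1-based inclusive
    coordinates tiling [1, length] in concatenation order. A taxon absent
    from a gene carries ``-`` across that gene's span.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        rows: dict[str, str],
        partitions: Sequence[tuple[str, int, int]],
    ):
        self.taxa = list(taxa)
        self.rows = rows
        self.partitions = list(partitions)
        self.length = partitions[-1][2] if partitions else 0
        for t in self.taxa:
            if len(rows[t]) != self.length:
                raise DataError(
                    f"row {t} has length {len(rows[t])}, matrix length {self.length}"
                )


def concatenate(
    ogs: Iterable, taxon_universe: Sequence[str] | None = None, sort_ogs: bool = True
) -> Supermatrix:
    """Concatenate OG alignments into a supermatrix.

    Each OG must carry at most one member per taxon (the pruner's job). The
    taxon set is the union of member taxa unless ``taxon_universe`` is
    given. OGs are ordered lexicographically by og_id by default for
    determinism; ``sort_ogs=False`` preserves input order.
    """
    ogs = list(ogs)
    if not ogs:
        raise EmptyInputError("nothing to concatenate")
    if sort_ogs:
        ogs = sorted(ogs, key=lambda og: og.og_id)
    for og in ogs:
        taxa_in_og = [m.taxon_id for m in og.members]
        if len(taxa_in_og) != len(set(taxa_in_og)):
            dup = sorted({t for t in taxa_in_og if taxa_in_og.count(t) > 1})
            raise DataError(
                f"OG {og.og_id} has multiple sequences for taxon {dup[0]}; "
                "run the pruner first"
            )
    if taxon_universe is not None:
        taxa = list(taxon_universe)
    else:
        taxa = sorted({m.taxon_id for og in ogs for m in og.members})

    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for og in ogs:
        by_taxon = {m.taxon_id: m.residues for m in og.members}
        for t in taxa:
            chunks[t].append(by_taxon.get(t, GAP * og.length))
        partitions.append((og.og_id, pos, pos + og.length - 1))
        pos += og.length
    rows = {t: "".join(chunks[t]) for t in taxa}
    return Supermatrix(taxa, rows, partitions)


def matrix_stats(sm: Supermatrix, missing_definition: str = "all_gaps") -> MatrixStats:
    """Occupancy statistics of a supermatrix.

    ``pct_missing`` is the percentage of ``-`` cells over the whole
    n_taxa x length grid; ``X`` counts as present data (it occupies a
    homologous position). With ``missing_definition='absent_taxon'`` only
    cells of genes a taxon is entirely absent from count as missing —
    internal alignment gaps do not.
    """
    if missing_definition not in ("all_gaps", "absent_taxon"):
        raise ValueError("missing_definition must be 'all_gaps' or 'absent_taxon'")
    n_taxa = len(sm.taxa)
    total_cells = n_taxa * sm.length
    per_taxon = {}
    missing_cells = 0
    for t in sm.taxa:
        row = sm.rows[t]
        gaps = row.count(GAP)
        per_taxon[t] = 100.0 * (sm.length - gaps) / sm.length if sm.length else 0.0
        if missing_definition == "all_gaps":
            missing_cells += gaps
    per_gene = {}
    for og_id, start, end in sm.partitions:
        span = slice(start - 1, end)
        count = sum(
            1 for t in sm.taxa if sm.rows[t][span].count(GAP) < (end - start + 1)
        )
        per_gene[og_id] = count
        if missing_definition == "absent_taxon":
            missing_cells += (n_taxa - count) * (end - start + 1)
    pct_missing = 100.0 * missing_cells / total_cells if total_cells else 0.0
    return MatrixStats(
        n_taxa=n_taxa,
        n_genes=len(sm.partitions),
        total_length=sm.length,
        pct_missing=pct_missing,
        per_taxon_occupancy=per_taxon,
        per_gene_taxon_count=per_gene,
    )


def write_supermatrix(
    sm: Supermatrix,
    out_prefix: str | Path,
    model: str = "AUTO",
    line_width: int = 60,
    missing_char: str = GAP,
) -> dict[str, Path]:
    """Write FASTA matrix + partition file + stats JSON + occupancy TSV.

    Returns the paths written, keyed by artefact name.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = out_prefix.with_suffix(".fasta")
    with fasta.open("w") as fh:
        for t in sm.taxa:
            row = sm.rows[t]
            if missing_char != GAP:
                row = row.replace(GAP, missing_char)
            fh.write(f">{t}\n")
            for i in range(0, len(row), line_width):
                fh.write(row[i : i + line_width] + "\n")
    partitions = out_prefix.with_suffix(".partitions.txt")
    write_partition_file(sm, partitions, model=model)
    stats = matrix_stats(sm)
    stats_path = out_prefix.with_suffix(".stats.json")
    stats_path.write_text(json.dumps(asdict(stats), indent=2) + "\n")
    occ_path = out_prefix.with_suffix(".occupancy.tsv")
    with occ_path.open("w") as fh:
        fh.write("taxon_id\tpct_occupancy\n")
        for t in sm.taxa:
            fh.write(f"{t}\t{stats.per_taxon_occupancy[t]:.4f}\n")
    return {
        "fasta": fasta,
        "partitions": partitions,
        "stats": stats_path,
        "occupancy": occ_path,
    }


def read_supermatrix_fasta(
    path: str | Path, partitions_path: str | Path | None = None
) -> Supermatrix:
    """Read a concatenated FASTA matrix (headers are taxon ids) and an
    optional RAxML partition file back into a :class:`Supermatrix`."""
    from Bio import SeqIO

    taxa, rows = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows[rec.id] = str(rec.seq).upper().replace("?", GAP).replace(".", GAP)
    if not taxa:
        raise EmptyInputError(f"{path}: no records")
    length = len(rows[taxa[0]])
    partitions: list[tuple[str, int, int]] = []
    if partitions_path is not None:
        for line in Path(partitions_path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            left, coords = line.rsplit("=", 1)
            og_id = left.split(",", 1)[1].strip()
            start, end = coords.strip().split("-")
            partitions.append((og_id, int(start), int(end)))
    else:
        partitions = [("all", 1, length)]
    return Supermatrix(taxa, rows, partitions)
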