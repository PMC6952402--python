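"""Synthetic orthologous groups with labelled artifacts.

The generator emulates the statistical structure the curation filters
assume: per OG, an ancestral amino-acid sequence evolves to each sampled
taxon by independent per-site substitution (star phylogeny — the tree-free
filters do not care about phylogenetic correlation), and labelled artifacts
are injected on top:

* **contaminant** — a fresh uniform-random sequence replacing a taxon's row;
  expected identity to the alignment consensus is ~5%, so its "change"
  value sits near 95, far above the 75 deletion threshold;
* **island** — a short run of random residues stranded between >= 10-gap
  flanks in one row, mimicking a mistranslated exon;
* **terminal_x** — an ``X`` within the terminal 20 residues, marking a
  low-quality end for the terminal-trim rule;
* **inparalog_extra** — a second, extra-diverged copy of a taxon's sequence;
* **fragment** — a short contiguous piece of the taxon's sequence, gaps
  elsewhere, below the minimum-length cut.

Every artifact is recorded in :class:`TruthLabels`, so a pipeline run on a
simulated dataset can be scored for per-class precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ConsistencyError
from .io import GAP, AlignedSequence, FilterReport, OGAlignment

AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

# Which pipeline stage is responsible for which artifact class; used to
# compute per-class precision (recall counts removal by ANY stage).
SEQ_STAGE_FOR_CLASS = {
    "fragment": "min_length",
    "contaminant": "change",
    "inparalog_extra": "prune",
}
SEG_STAGE_FOR_KIND = {"island": "islands", "terminal_x": "xtrim"}


@dataclass
class SimParams:
    """Generator settings; defaults are the benchmark study conditions."""

    n_taxa: int = 40
    n_ogs: int = 50
    og_len_range: tuple[int, int] = (150, 300)
    divergence: float = 0.05
    occupancy: float = 0.9
    p_contaminant: float = 0.1
    p_inparalog: float = 0.0
    p_fragment: float = 0.0
    p_island: float = 0.2
    p_term_x: float = 0.1
    island_len_range: tuple[int, int] = (5, 20)
    island_flank_range: tuple[int, int] = (10, 15)
    fragment_len_range: tuple[int, int] = (30, 90)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        for name in ("divergence", "occupancy", "p_contaminant", "p_inparalog",
                     "p_fragment", "p_island", "p_term_x"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_contaminant + self.p_inparalog + self.p_fragment > 1.0:
            raise ValueError("sequence-class probabilities sum above 1")
        for name in ("og_len_range", "island_len_range", "island_flank_range",
                     "fragment_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a non-empty positive range")

    @property
    def taxa(self) -> list[str]:
        return [f"t{i + 1:02d}" for i in range(self.n_taxa)]


@dataclass
class TruthLabels:
    """Ground truth: one class per generated sequence, plus segment-level
    artifact annotations (0-based half-open alignment-column spans)."""

    classes: dict[tuple[str, str], str] = field(default_factory=dict)
    segments: list[tuple[str, str, int, int, str]] = field(default_factory=list)

    def merge(self, other: "TruthLabels") -> None:
        self.classes.update(other.classes)
        self.segments.extend(other.segments)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return AA[rng.integers(0, len(AA), size=length)]


def _mutate(rng: np.random.Generator, ancestor: np.ndarray, p: float) -> np.ndarray:
    """Independent per-site substitution, replacement uniform over the other
    19 letters."""
    out = ancestor.copy()
    hits = np.nonzero(rng.random(len(ancestor)) < p)[0]
    for i in hits:
        choices = AA[AA != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def simulate_og(
    params: SimParams, og_index: int, rng: np.random.Generator
) -> tuple[OGAlignment, TruthLabels]:
    og_id = f"og{og_index:04d}"
    lo, hi = params.og_len_range
    length = int(rng.integers(lo, hi + 1))
    ilo, ihi = params.island_len_range
    flo, fhi = params.island_flank_range
    margin = 25  # residues kept clean on each side of an injected island
    if params.p_island > 0 and ihi + 2 * fhi + 2 * margin > lo:
        raise ValueError(
            "island plus flanks plus margins do not fit the shortest OG; "
            "shrink island_len_range/island_flank_range or lengthen OGs"
        )
    ancestor = _random_seq(rng, length)
    truth = TruthLabels()
    members: list[AlignedSequence] = []
    seq_counter = 0

    for taxon in params.taxa:
        if rng.random() >= params.occupancy:
            continue
        seq_counter += 1
        seq_id = f"s{seq_counter}"
        u = rng.random()
        if u < params.p_contaminant:
            cls = "contaminant"
            row = _random_seq(rng, length)
        elif u < params.p_contaminant + params.p_inparalog:
            cls = "inparalog"  # handled below: clean copy + extra copy
            row = _mutate(rng, ancestor, params.divergence)
        elif u < params.p_contaminant + params.p_inparalog + params.p_fragment:
            cls = "fragment"
            frag_len = int(rng.integers(*params.fragment_len_range) )
            frag_len = min(frag_len, length)
            start = int(rng.integers(0, length - frag_len + 1))
            base = _mutate(rng, ancestor, params.divergence)
            row = np.full(length, GAP.encode(), dtype="S1")
            row[start : start + frag_len] = base[start : start + frag_len]
        else:
            cls = "clean"
            row = _mutate(rng, ancestor, params.divergence)

        if cls == "clean":
            v = rng.random()
            if v < params.p_island:
                ilen = int(rng.integers(ilo, ihi + 1))
                flank = int(rng.integers(flo, fhi + 1))
                a = int(rng.integers(margin + flank, length - margin - flank - ilen + 1))
                row[a - flank : a] = GAP.encode()
                row[a : a + ilen] = _random_seq(rng, ilen)
                row[a + ilen : a + ilen + flank] = GAP.encode()
                truth.segments.append((og_id, seq_id, a, a + ilen, "island"))
            elif v < params.p_island + params.p_term_x:
                window = min(20, length)
                j = int(rng.integers(0, window))
                if rng.random() < 0.5:
                    row[j] = b"X"
                    truth.segments.append((og_id, seq_id, 0, j + 1, "terminal_x"))
                else:
                    row[length - 1 - j] = b"X"
                    truth.segments.append(
                        (og_id, seq_id, length - 1 - j, length, "terminal_x")
                    )

        member = AlignedSequence(taxon, seq_id, row.tobytes().decode("ascii"))
        if cls == "inparalog":
            truth.classes[(og_id, seq_id)] = "clean"
            members.append(member)
            seq_counter += 1
            extra_id = f"s{seq_counter}"
            extra = _mutate(rng, row, params.divergence)
            truth.classes[(og_id, extra_id)] = "inparalog_extra"
            members.append(
                AlignedSequence(taxon, extra_id, extra.tobytes().decode("ascii"))
            )
        else:
            truth.classes[(og_id, seq_id)] = cls
            members.append(member)

    return OGAlignment(og_id, members), truth


def simulate_dataset(
    params: SimParams,
) -> tuple[list[OGAlignment], TruthLabels, dict]:
    """Generate ``n_ogs`` independent OGs from one seeded stream."""
    rng = np.random.default_rng(params.seed)
    truth = TruthLabels()
    ogs = []
    for i in range(params.n_ogs):
        og, t = simulate_og(params, i, rng)
        ogs.append(og)
        truth.merge(t)
    manifest = {"params": asdict(params), "n_sequences": sum(len(o) for o in ogs)}
    return ogs, truth, manifest


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return False
    return inter >= 0.5 * (a[1] - a[0]) and inter >= 0.5 * (b[1] - b[0])


def score_recovery(
    truth: TruthLabels, reports: Sequence[FilterReport]
) -> dict[str, dict[str, float | None]]:
    """Per-artifact-class precision and recall of a pipeline run.

    Recall counts a truth item as recovered if any stage removed it —
    including removal of its whole sequence or OG (either way the artifact
    is gone from the final matrix). Precision is judged against the stage
    responsible for the class (see ``SEQ_STAGE_FOR_CLASS`` /
    ``SEG_STAGE_FOR_KIND``); it is ``None`` when that stage removed
    nothing. Segment matching requires >= 50% reciprocal overlap.
    """
    truth_ogs = {og for og, _ in truth.classes}
    removed_seq: set[tuple[str, str]] = set()
    removed_ogs: set[str] = set()
    by_stage_seq: dict[str, list[tuple[str, str, str]]] = {}
    by_stage_seg: dict[str, list[tuple[str, str, int, int]]] = {}
    for rep in reports:
        for og, _tax, sid, reason in rep.removed_sequences:
            if og not in truth_ogs:
                raise ConsistencyError(f"report references unknown OG {og!r}")
            removed_seq.add((og, sid))
            by_stage_seq.setdefault(rep.stage_name, []).append((og, sid, reason))
        for og, reason in rep.removed_ogs:
            removed_ogs.add(og)
        for og, sid, start, end in rep.masked_segments:
            by_stage_seg.setdefault(rep.stage_name, []).append((og, sid, start, end))

    def gone(og: str, sid: str) -> bool:
        return (og, sid) in removed_seq or og in removed_ogs

    scores: dict[str, dict[str, float | None]] = {}
    for cls, stage in SEQ_STAGE_FOR_CLASS.items():
        truth_items = [k for k, c in truth.classes.items() if c == cls]
        recall = (
            sum(1 for og, sid in truth_items if gone(og, sid)) / len(truth_items)
            if truth_items
            else None
        )
        stage_removed = by_stage_seq.get(stage, [])
        if cls == "inparalog_extra":
            stage_removed = [r for r in stage_removed if r[2] == "inparalog_shorter"]
        precision = (
            sum(
                1
                for og, sid, _ in stage_removed
                if truth.classes.get((og, sid)) == cls
            )
            / len(stage_removed)
            if stage_removed
            else None
        )
        scores[cls] = {"precision": precision, "recall": recall}

    for kind, stage in SEG_STAGE_FOR_KIND.items():
        truth_segs = [s for s in truth.segments if s[4] == kind]
        masked = by_stage_seg.get(stage, [])
        matched_truth = 0
        for og, sid, start, end, _ in truth_segs:
            hit = any(
                m_og == og and m_sid == sid
                and _reciprocal_overlap((start, end), (m_start, m_end))
                for m_og, m_sid, m_start, m_end in masked
            )
            if hit or gone(og, sid):
                matched_truth += 1
        recall = matched_truth / len(truth_segs) if truth_segs else None
        matched_masked = sum(
            1
            for m_og, m_sid, m_start, m_end in masked
            if any(
                og == m_og and sid == m_sid
                and _reciprocal_overlap((start, end), (m_start, m_end))
                for og, sid, start, end, k in truth.segments
                if k == kind
            )
        )
        precision = matched_masked / len(masked) if masked else None
        scores[kind] = {"precision": precision, "recall": recall}
    return scores
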