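"""Tree-based paralog pruning.

When a taxon is represented by several sequences in an OG (splice variants,
inparalogs, overlooked paralogs, contamination), the gene tree decides which
one to keep:

* taxa whose copies form a monophyletic group on the unrooted, support-
  collapsed tree are inparalogs — keep the copy with the most residues;
* if non-monophyletic duplication remains, the tree is cut at every edge and
  the single-copy subtree retaining the most distinct taxa is kept, the rest
  of the leaves discarded as paralogs.

All tie-breaks are fixed so the procedure is deterministic: equal-length
inparalogs break to the lexicographically smallest label; equally good
subtrees break by leaf count, then total residue count, then smallest
sorted-label tuple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConsistencyError, DataError, HeaderError
from .io import FilterReport, OGAlignment
from .trees import GeneTree


@dataclass
class PruneResult:
    kept: set[str]
    dropped: dict[str, str] = field(default_factory=dict)  # label -> reason
    collapsed_node_count: int = 0

    def __post_init__(self) -> None:
        overlap = self.kept & set(self.dropped)
        if overlap:
            raise ConsistencyError(f"labels both kept and dropped: {sorted(overlap)}")


def _taxon_of(label: str) -> str:
    if "|" not in label:
        raise HeaderError(f"leaf label {label!r} lacks '|' (expected taxon|seqid)")
    return label.split("|", 1)[0]


def _edge_leaf_sets(tree: GeneTree) -> list[frozenset[str]]:
    """Leaf-label set below each non-seed node (one side of each edge's
    bipartition on the unrooted tree)."""
    below: dict[int, frozenset[str]] = {}
    sets = []
    for nd in tree.dendropy_tree.postorder_node_iter():
        if not nd.child_nodes():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(
                *(below[id(ch)] for ch in nd.child_nodes())
            )
        if nd.parent_node is not None:
            sets.append(below[id(nd)])
    return sets


def prune_to_single_copy(
    tree: GeneTree, seq_nongap_len: Mapping[str, int]
) -> PruneResult:
    """Select at most one sequence per taxon from a collapsed gene tree.

    ``seq_nongap_len`` maps every leaf label to the sequence's residue
    count, the "best sequence" metric for inparalog resolution and subtree
    tie-breaking.
    """
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        raise DataError("gene tree has duplicate leaf labels")
    for lab in labels:
        if lab not in seq_nongap_len:
            raise DataError(f"no sequence length for leaf {lab!r}")
    by_taxon: dict[str, list[str]] = {}
    for lab in labels:
        by_taxon.setdefault(_taxon_of(lab), []).append(lab)

    dropped: dict[str, str] = {}
    multi = {t: labs for t, labs in by_taxon.items() if len(labs) > 1}
    if not multi:
        return PruneResult(kept=set(labels), dropped={},
                           collapsed_node_count=tree.collapsed_node_count)

    all_leaves = frozenset(labels)
    edge_sets = _edge_leaf_sets(tree)

    # (b) monophyletic duplicates are inparalogs: keep the longest copy.
    for taxon, labs in multi.items():
        group = frozenset(labs)
        mono = group == all_leaves or any(
            s == group or (all_leaves - s) == group for s in edge_sets
        )
        if mono:
            best = min(labs, key=lambda lab: (-seq_nongap_len[lab], lab))
            for lab in labs:
                if lab != best:
                    dropped[lab] = "inparalog_shorter"

    remaining = [lab for lab in labels if lab not in dropped]
    rem_by_taxon: dict[str, list[str]] = {}
    for lab in remaining:
        rem_by_taxon.setdefault(_taxon_of(lab), []).append(lab)

    if all(len(labs) == 1 for labs in rem_by_taxon.values()):
        return PruneResult(kept=set(remaining), dropped=dropped,
                           collapsed_node_count=tree.collapsed_node_count)

    # (c) non-monophyletic duplication: cut every edge of the unrooted tree
    # and keep the best subtree in which every taxon occurs at most once.
    # Restricting each bipartition side to the leaves surviving (b) yields
    # exactly the splits of the reduced tree.
    rem_set = frozenset(remaining)
    candidates: set[frozenset[str]] = set()
    for s in edge_sets:
        for side in (s & rem_set, rem_set - s):
            if side:
                candidates.add(side)

    def single_copy(side: frozenset[str]) -> bool:
        taxa = [_taxon_of(lab) for lab in side]
        return len(taxa) == len(set(taxa))

    valid = [side for side in candidates if single_copy(side)]
    if not valid:  # degenerate; cannot happen on a tree with >= 1 leaf
        raise ConsistencyError("no single-copy subtree found")

    def score(side: frozenset[str]):
        taxa = {_taxon_of(lab) for lab in side}
        total_len = sum(seq_nongap_len[lab] for lab in side)
        return (len(taxa), len(side), total_len)

    best_score = max(score(side) for side in valid)
    best_side = min(
        (side for side in valid if score(side) == best_score),
        key=lambda side: tuple(sorted(side)),
    )
    for lab in remaining:
        if lab not in best_side:
            dropped[lab] = "paralog_pruned"
    return PruneResult(kept=set(best_side), dropped=dropped,
                       collapsed_node_count=tree.collapsed_node_count)


def apply_prune(
    aln: OGAlignment, result: PruneResult
) -> tuple[OGAlignment, FilterReport]:
    """Restrict an alignment to the pruner's kept labels, preserving input
    order; removals are reported with the pruner's reasons."""
    report = FilterReport("prune")
    member_labels = {m.label for m in aln.members}
    unknown = (result.kept | set(result.dropped)) - member_labels
    if unknown:
        raise ConsistencyError(
            f"OG {aln.og_id}: prune result references labels not in the "
            f"alignment: {sorted(unknown)[:5]}"
        )
    kept_members = []
    for m in aln.members:
        if m.label in result.kept:
            kept_members.append(m)
        elif m.label in result.dropped:
            report.removed_sequences.append(
                (aln.og_id, m.taxon_id, m.seq_id, result.dropped[m.label])
            )
        else:
            # Leaf absent from the tree entirely: treat as pruned.
            report.removed_sequences.append(
                (aln.og_id, m.taxon_id, m.seq_id, "paralog_pruned")
            )
    return aln.replace_members(kept_members), report
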