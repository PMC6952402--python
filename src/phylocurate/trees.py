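"""Gene trees: newick parsing and low-support node collapsing.

Gene trees arrive from upstream per-gene tree inference with bootstrap-style
support values as internal node labels in ``[0, 100]``. A missing label means
*unknown* support, which is never treated as zero: only nodes whose support
is present and below the threshold are collapsed into polytomies.

Trees are consumed, not built, and for paralog pruning they are treated as
unrooted — the rooting in the newick string is an artefact of serialisation.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

from .errors import HeaderError, NewickParseError


def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        return float(label)
    except ValueError:
        return None


class GeneTree:
    """Thin wrapper around a dendropy tree with ``taxon|seqid`` leaves."""

    def __init__(self, tree: dendropy.Tree, collapsed_node_count: int = 0):
        self._tree = tree
        self.collapsed_node_count = collapsed_node_count

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several reader error types
            raise NewickParseError(f"malformed newick: {exc}") from exc
        gt = cls(tree)
        for label in gt.leaf_labels():
            if "|" not in label:
                raise HeaderError(
                    f"leaf label {label!r} lacks '|' (expected taxon|seqid)"
                )
        return gt

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def leaf_taxa(self) -> list[str]:
        """Taxon part of each leaf label (before the first '|')."""
        return [lab.split("|", 1)[0] for lab in self.leaf_labels()]

    def internal_supports(self) -> list[float | None]:
        """Supports of internal, non-seed nodes in postorder."""
        out = []
        for nd in self._tree.postorder_node_iter():
            if nd.parent_node is not None and nd.child_nodes():
                out.append(_parse_support(nd.label))
        return out

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def read_newick(path: str | Path) -> GeneTree:
    """Read a single-tree newick file.

    Numeric internal-node labels become support values; non-numeric or
    absent labels are missing support. Polytomies are preserved.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise NewickParseError(f"{path}: empty newick file")
    return GeneTree.from_newick(text)


def collapse_low_support(tree: GeneTree, collapse_support: float = 50) -> GeneTree:
    """Contract internal edges whose child-node support is below threshold.

    Strict: a node with support exactly equal to ``collapse_support``
    survives; a node with no support value survives. The leaf set is
    unchanged; collapsing creates polytomies. Returns a new tree; the input
    is untouched. The number of contracted edges is recorded on the result's
    ``collapsed_node_count``.
    """
    work = GeneTree.from_newick(tree.to_newick() + ";" if not tree.to_newick().endswith(";") else tree.to_newick())
    t = work._tree
    count = 0
    for nd in list(t.postorder_node_iter()):
        if nd.parent_node is None or not nd.child_nodes():
            continue
        support = _parse_support(nd.label)
        if support is not None and support < collapse_support:
            parent = nd.parent_node
            idx = parent.child_nodes().index(nd)
            for offset, ch in enumerate(list(nd.child_nodes())):
                nd.remove_child(ch)
                parent.insert_child(idx + offset, ch)
            parent.remove_child(nd)
            count += 1
    return GeneTree(t, collapsed_node_count=count)
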