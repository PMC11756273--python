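"""Newick tree reading, writing and the topology queries curation needs.

A :class:`Tree` wraps a dendropy tree with a private taxon namespace and
exposes exactly what the rest of the package uses: leaf labels, branch
lengths, bipartition-based monophyly on unrooted trees, and pruning with
suppression of degree-2 nodes (branch lengths summed).

Monophyly is defined for unrooted trees: a leaf set is monophyletic iff it
forms one side of some bipartition (edge) of the tree.  Gene trees handled
by the curation filters are unrooted and no rooting rule is assumed.
"""

from __future__ import annotations

from typing import Iterable

import dendropy


class NewickParseError(ValueError):
    """Raised for malformed Newick input; message carries position context."""


class Tree:
    """A phylogenetic tree with unique leaf labels and optional branch lengths."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate leaf labels: {sorted(dupes)}")
        self._leaf_labels = labels

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return parse_newick(text)

    @classmethod
    def from_file(cls, path) -> "Tree":
        with open(path) as fh:
            return parse_newick(fh.read())

    def copy(self) -> "Tree":
        return Tree(self._tree.clone(depth=1))

    # -- basic queries ----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    def branch_lengths(self, pool: str = "all") -> list[float]:
        """Branch lengths of the tree; ``pool`` is 'all' or 'terminal'.

        Edges without a defined length (typically the root edge) are skipped.
        """
        out = []
        for edge in self._tree.preorder_edge_iter():
            if edge.length is None:
                continue
            if pool == "terminal" and not edge.head_node.is_leaf():
                continue
            out.append(float(edge.length))
        return out

    def terminal_branch_length(self, label: str) -> float:
        node = self._find_leaf(label)
        if node.edge.length is None:
            raise ValueError(f"leaf {label!r} has no branch length")
        return float(node.edge.length)

    def total_length(self) -> float:
        return sum(self.branch_lengths())

    def require_branch_lengths(self) -> None:
        """Raise if any non-root edge lacks a length or has a negative one."""
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                head = edge.head_node
                name = head.taxon.label if head.is_leaf() else "internal node"
                raise ValueError(f"edge leading to {name} has no branch length")
            if edge.length < 0:
                raise ValueError("negative branch length encountered")

    def _find_leaf(self, label: str):
        for lf in self._tree.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise KeyError(f"leaf {label!r} not in tree")

    # -- topology queries --------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each reported as the smaller-or-canonical side."""
        all_leaves = frozenset(self._leaf_labels)
        out = set()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def is_monophyletic(self, leaves: Iterable[str]) -> bool:
        """True iff ``leaves`` forms one side of a bipartition of the unrooted tree."""
        query = frozenset(leaves)
        all_leaves = frozenset(self._leaf_labels)
        unknown = query - all_leaves
        if unknown:
            raise KeyError(f"labels not in tree: {sorted(unknown)}")
        if not query:
            raise ValueError("empty leaf set")
        if len(query) in (1, len(all_leaves)):
            return True
        complement = all_leaves - query
        if len(complement) == 1:
            return True
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if side == query or side == complement:
                return True
        # Unrooted reading of a rooted representation: the clades hanging off
        # the seed node partition the leaves; a union of all but one child of
        # the root is also one side of a bipartition.
        root = self._tree.seed_node
        children = root.child_nodes()
        if len(children) >= 2:
            for child in children:
                side = all_leaves - frozenset(lf.taxon.label for lf in child.leaf_iter())
                if side == query or side == complement:
                    return True
        return False

    # -- editing -----------------------------------------------------------

    def prune_leaves(self, leaves: Iterable[str]) -> "Tree":
        """Return a copy with ``leaves`` removed and degree-2 nodes suppressed.

        Branch lengths across suppressed nodes are summed.  Pruning to fewer
        than two leaves is an error.
        """
        drop = set(leaves)
        unknown = drop - set(self._leaf_labels)
        if unknown:
            raise KeyError(f"labels not in tree: {sorted(unknown)}")
        if not drop:
            return self.copy()
        keep = [l for l in self._leaf_labels if l not in drop]
        if len(keep) < 2:
            raise ValueError("pruning would leave fewer than two leaves")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in drop]
        clone.prune_taxa(taxa, suppress_unifurcations=True)
        # dendropy may leave a unifurcating seed node; collapse it, adding lengths.
        clone.suppress_unifurcations()
        return Tree(clone)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s + ("" if s.endswith(";") else ";")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_leaves} leaves)"


def parse_newick(text: str) -> Tree:
    """Parse a Newick string; raises :class:`NewickParseError` with context."""
    if text.count("(") != text.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"could not parse Newick: {exc}") from exc
    return Tree(dtree)
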