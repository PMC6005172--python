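"""Unrooted-tree operations for contaminant pruning and suboptimal-tree sets.

All topology questions here are asked of *unrooted* trees: a clade is a side
of a bipartition (the two leaf sets induced by deleting one edge), monophyly
of a group means some edge separates exactly that group from everything
else, and two trees are "the same" when their nontrivial bipartition sets
coincide.  Trees are stored internally as (arbitrarily) rooted dendropy
trees; nothing below depends on the root placement.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "PruneResult",
    "read_newick",
    "write_newick",
    "is_monophyletic",
    "prune_to_monophyly",
    "shuffle_clades_of_three",
    "dedupe_trees",
]

logger = logging.getLogger(__name__)


class PhyloTree:
    """A leaf-labeled, branch-length-bearing tree with optional class labels.

    Parameters
    ----------
    tree:
        A dendropy tree.  The rooting is treated as a drawing artefact.
    leaf_classes:
        Optional mapping leaf label -> taxon-class label (free-form text,
        typically one of the domain classes used by the scoring screen).
    query:
        Label of the (at most one) query leaf.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        leaf_classes: dict[str, str] | None = None,
        query: str | None = None,
    ):
        self._tree = tree
        self.leaf_classes = dict(leaf_classes or {})
        self.query = query
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if query is not None and query not in set(labels):
            raise ValueError(f"query leaf {query!r} not in tree")

    # -- basic accessors -------------------------------------------------
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self._tree.clone(depth=1), dict(self.leaf_classes), self.query
        )

    def total_branch_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter() if e.head_node
        )

    # -- bipartitions ----------------------------------------------------
    def clade_sets(self) -> list[frozenset[str]]:
        """Leaf set below every node of the rooted representation."""
        below: dict[int, frozenset[str]] = {}
        out = []
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                s = frozenset([node.taxon.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = s
            out.append(s)
        return out

    def bipartitions(self, nontrivial_only: bool = True) -> frozenset[frozenset[str]]:
        """Unrooted splits, each normalized to the side excluding the
        lexicographically smallest leaf."""
        leaves = self.leaf_set()
        anchor = min(leaves)
        n = len(leaves)
        splits = set()
        for below in self.clade_sets():
            side = leaves - below if anchor in below else below
            if nontrivial_only and not (2 <= len(side) <= n - 2):
                continue
            if not nontrivial_only and not (1 <= len(side) <= n - 1):
                continue
            splits.add(side)
        return frozenset(splits)

    def same_topology(self, other: "PhyloTree") -> bool:
        if self.leaf_set() != other.leaf_set():
            return False
        return self.bipartitions() == other.bipartitions()

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        text: str,
        leaf_classes: dict[str, str] | None = None,
        query: str | None = None,
    ) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"invalid newick: {exc}") from exc
        return cls(tree, leaf_classes, query)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()


@dataclass
class PruneResult:
    """Outcome of contaminant pruning toward group monophyly."""

    pruned_tree: PhyloTree
    removed_leaves: list[str]
    success: bool


def read_newick(text: str, **kwargs) -> PhyloTree:
    """Parse a Newick string (multifurcations allowed, duplicate leaves rejected)."""
    return PhyloTree.from_newick(text, **kwargs)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def _restricted_monophyly(
    clade_sets: Iterable[frozenset[str]],
    leaves: frozenset[str],
    group: frozenset[str],
    removed: frozenset[str],
) -> bool:
    """Monophyly of ``group - removed`` on the tree restricted to
    ``leaves - removed``, decided from the full tree's clade sets.

    Restriction commutes with taking sides of bipartitions, so a split of
    the restricted tree is the restriction of some split of the full tree.
    """
    kept = leaves - removed
    target = group - removed
    if len(target) <= 1 or len(kept - target) <= 1:
        return True
    for below in clade_sets:
        side = below & kept
        if side == target or side == kept - target:
            return True
    return False


def is_monophyletic(tree: PhyloTree, group: Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree splits off exactly ``group``.

    Groups of size 1 and of size n are monophyletic by definition.
    """
    group = frozenset(group)
    if not group:
        raise ValueError("group must be non-empty")
    leaves = tree.leaf_set()
    unknown = group - leaves
    if unknown:
        raise ValueError(f"leaves not in tree: {sorted(unknown)}")
    return _restricted_monophyly(tree.clade_sets(), leaves, group, frozenset())


def prune_to_monophyly(
    tree: PhyloTree,
    group: Iterable[str],
    protected: Iterable[str] = (),
    max_prune: int = 2,
) -> PruneResult:
    """Smallest removal of group members that restores group monophyly.

    Mirrors the contaminant rule used when RefSeq mislabels place stray
    "animal" sequences outside the main animal clade: up to ``max_prune``
    group members (never the protected query, never non-group leaves) may
    be deleted.  Subsets are tried in order of size 0, 1, ..., max_prune;
    equal-size ties go to the lexicographically smallest leaf-label tuple.
    """
    group = frozenset(group)
    protected = frozenset(protected)
    leaves = tree.leaf_set()
    unknown = group - leaves
    if unknown:
        raise ValueError(f"leaves not in tree: {sorted(unknown)}")
    removable = sorted(group - protected)
    clade_sets = tree.clade_sets()

    for size in range(0, max_prune + 1):
        for subset in combinations(removable, size):
            removed = frozenset(subset)
            if _restricted_monophyly(clade_sets, leaves, group, removed):
                pruned = tree.copy()
                if removed:
                    pruned.dendropy_tree.prune_taxa_with_labels(
                        list(subset), suppress_unifurcations=True
                    )
                return PruneResult(
                    pruned_tree=pruned, removed_leaves=list(subset), success=True
                )
    return PruneResult(pruned_tree=tree.copy(), removed_leaves=[], success=False)


def _disjoint(nodes, below) -> bool:
    sets = [below[id(n)] for n in nodes]
    for a, b in combinations(sets, 2):
        if a & b:
            return False
    return True


def shuffle_clades_of_three(
    tree: PhyloTree, n_trees: int, seed: int
) -> list[PhyloTree]:
    """Suboptimal-tree generator: cyclically exchange three small clades.

    Each output tree picks three disjoint clades of size <= 3 uniformly at
    random and rotates their attachment points (clade 1's position receives
    clade 2, and so on).  Outputs are deduplicated against each other and
    against the input topology; deterministic under a fixed seed.
    """
    if n_trees <= 0:
        raise ValueError("n_trees must be positive")
    if len(tree) < 9:
        logger.warning(
            "tree has %d leaves (< 9); shuffling whatever clades exist", len(tree)
        )
    rng = random.Random(seed)
    seen = {tree.bipartitions()}
    out: list[PhyloTree] = []
    max_attempts = 200 * n_trees
    for _ in range(max_attempts):
        if len(out) >= n_trees:
            break
        work = tree.copy()
        dtree = work.dendropy_tree
        below = {}
        candidates = []
        for node in dtree.postorder_node_iter():
            if node.is_leaf():
                s = frozenset([node.taxon.label])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
            below[id(node)] = s
            if node.parent_node is not None and len(s) <= 3:
                candidates.append(node)
        if len(candidates) < 3:
            logger.warning("fewer than 3 shuffle-eligible clades; stopping")
            break
        picked = None
        for _try in range(50):
            trio = rng.sample(candidates, 3)
            if _disjoint(trio, below):
                picked = trio
                break
        if picked is None:
            continue
        parents = [n.parent_node for n in picked]
        lengths = [n.edge.length for n in picked]
        for n, p in zip(picked, parents):
            p.remove_child(n)
        # cyclic exchange: position i receives clade i+1; the attachment
        # position keeps its original branch length
        for i, p in enumerate(parents):
            incoming = picked[(i + 1) % 3]
            p.add_child(incoming)
            incoming.edge.length = lengths[i]
        shuffled = PhyloTree(dtree, dict(tree.leaf_classes), tree.query)
        key = shuffled.bipartitions()
        if key in seen:
            continue
        seen.add(key)
        out.append(shuffled)
    if len(out) < n_trees:
        logger.warning("produced %d of %d requested shuffled trees", len(out), n_trees)
    return out


def dedupe_trees(trees: Sequence[PhyloTree]) -> list[PhyloTree]:
    """Keep the first representative of each unrooted topology.

    Topology identity is equality of nontrivial bipartition sets; branch
    lengths and rootings are ignored.  All trees must share one leaf set.
    """
    if not trees:
        return []
    leaf_set = trees[0].leaf_set()
    seen: set[frozenset[frozenset[str]]] = set()
    out = []
    for t in trees:
        if t.leaf_set() != leaf_set:
            raise ValueError("trees do not share a common leaf set")
        key = t.bipartitions()
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out
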