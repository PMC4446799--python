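"""Dated species tree utilities.

The species tree is rooted, binary and ultrametric with branch lengths in
millions of years (my); leaf depths therefore all equal the root age.  Every
branch gets a stable identifier derived from the leaf set below it, so that
gain/loss events can be reported reproducibly ("branch above the MRCA of
{mouse, rat}").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy

from .types import ValidationError

ULTRAMETRIC_RTOL = 1e-6


def branch_id_for(leaves: Iterable[str]) -> str:
    """Stable branch identifier: sorted leaf labels joined with '+'."""
    return "+".join(sorted(leaves))


@dataclass
class SpeciesTree:
    """Rooted ultrametric species tree with branch lengths in my."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("species tree has duplicate leaf labels")
        depths = {}
        for node in self.tree.preorder_node_iter():
            el = node.edge.length
            if node.parent_node is None:
                el = 0.0 if el is None else el
            elif el is None:
                raise ValidationError("species tree has a branch without a length")
            if el < 0:
                raise ValidationError("species tree has a negative branch length")
            parent_depth = depths[id(node.parent_node)] if node.parent_node else 0.0
            depths[id(node)] = parent_depth + el
        leaf_depths = [depths[id(lf)] for lf in self.tree.leaf_node_iter()]
        dmax = max(leaf_depths)
        tol = max(dmax, 1.0) * ULTRAMETRIC_RTOL
        if dmax - min(leaf_depths) > tol:
            raise ValidationError(
                f"species tree is not ultrametric: leaf depths span "
                f"[{min(leaf_depths):g}, {dmax:g}]"
            )
        self._depth_below: dict[int, float] = {}
        self._root_age = dmax
        for node in self.tree.postorder_node_iter():
            # age of a node = my from the node down to any of its leaves
            self._depth_below[id(node)] = self._root_age - depths[id(node)]
        self._leaves = sorted(labels)

    # -- basic views ------------------------------------------------------

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaves)

    @property
    def root_age(self) -> float:
        return self._root_age

    def node_age(self, node: dendropy.Node) -> float:
        return self._depth_below[id(node)]

    def leaves_below(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def branch_id(self, node: dendropy.Node) -> str:
        return branch_id_for(self.leaves_below(node))

    def node_for_branch_id(self, branch_id: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if self.branch_id(node) == branch_id:
                return node
        raise KeyError(f"no branch with id {branch_id!r}")

    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        species = list(species)
        for s in species:
            if s not in self._leaves:
                raise KeyError(f"unknown species label {s!r}")
        node = self.tree.mrca(taxon_labels=species)
        if node is None:
            raise KeyError(f"no MRCA found for {species}")
        return node

    def divergence_time(self, species_a: str, species_b: str) -> float:
        """Age (my) of the most recent common ancestor of two leaves.

        Symmetric in its arguments; 0 for a species against itself.
        """
        if species_a == species_b:
            if species_a not in self._leaves:
                raise KeyError(f"unknown species label {species_a!r}")
            return 0.0
        return self.node_age(self.mrca([species_a, species_b]))

    def restrict_to(self, species: Iterable[str]) -> "SpeciesTree":
        """Subtree induced by a subset of species (branch lengths preserved)."""
        keep = set(species)
        missing = keep - set(self._leaves)
        if missing:
            raise KeyError(f"unknown species labels {sorted(missing)}")
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        # retain_taxa can leave a root edge carrying the pruned depth; the
        # subtree need not reach the original root age, only stay ultrametric
        return SpeciesTree(clone)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_species_tree(path) -> SpeciesTree:
    """Read a dated, ultrametric species tree from a newick file."""
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return SpeciesTree(tree)


def species_tree_from_newick(newick: str) -> SpeciesTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return SpeciesTree(tree)


def write_species_tree(tree: SpeciesTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_newick() + "\n")
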