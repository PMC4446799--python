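"""Gene trees and parental-origin classification.

Gene-family trees are built by neighbor joining (Saitou–Nei) on
Jukes–Cantor-corrected nucleotide distances from the codon-threaded
alignment, with bipartition supports from codon-column bootstrap
resampling.  The parental origin of an autosomal copy (or clade of copies
sharing one insertion) is read off the rooted tree: if its sister group
consists solely of Y-linked copies with sufficient bootstrap support the
copy descends from the Y gametolog, symmetrically for X; anything else is
unresolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .align import MultipleAlignment
from .types import AnalysisConfig, ValidationError

log = logging.getLogger("yrescue.phylo")

JC_MAX_DISTANCE = 5.0  # stand-in for saturated (p >= 3/4) pairs


@dataclass
class PhyloTree:
    """Unrooted gene tree with optional bootstrap supports per split.

    Splits are canonical bipartitions: the side NOT containing the
    alphabetically smallest taxon.  ``split_supports`` maps each nontrivial
    split of the tree to a percent in [0, 100]; ``uninformative`` flags
    alignments with no variable codon columns, for which supports carry no
    information and are reported as None.
    """

    newick: str
    taxa: tuple[str, ...]
    splits: frozenset[frozenset[str]]
    split_supports: dict = field(default_factory=dict)
    uninformative: bool = False

    def support_for(self, side: frozenset[str]) -> Optional[float]:
        """Bootstrap percent for the bipartition separating ``side`` from
        the rest; 100 for trivial splits (always present)."""
        if self.uninformative:
            return None
        comp = frozenset(self.taxa) - side
        if len(side) <= 1 or len(comp) <= 1:
            return 100.0
        canon = self.canonical(side)
        return self.split_supports.get(canon)

    def canonical(self, side) -> frozenset[str]:
        anchor = min(self.taxa)
        side = frozenset(side)
        return frozenset(self.taxa) - side if anchor in side else side


@dataclass(frozen=True)
class OriginCall:
    family: str
    clade: frozenset[str]        # autosomal copy labels classified
    verdict: str                 # X | Y | unresolved
    support: Optional[float]
    sister_taxa: frozenset[str]


# ---------------------------------------------------------------------------
# Distances

def _encode(alignment: MultipleAlignment) -> np.ndarray:
    mapping = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT", start=1):
        mapping[ord(b)] = i
    rows = np.frombuffer(
        "".join(alignment.rows).encode(), dtype=np.uint8
    ).reshape(len(alignment.rows), -1)
    return mapping[rows]  # 0 = gap/N/other, 1..4 = A,C,G,T


def _pair_stats_per_codon(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    """Per ordered pair (i<j): per-codon-column counts of valid positions
    and differing positions."""
    n, L = enc.shape
    ncod = L // 3
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valids = np.empty((len(pairs), ncod), dtype=np.float64)
    diffs = np.empty((len(pairs), ncod), dtype=np.float64)
    for k, (i, j) in enumerate(pairs):
        valid = (enc[i] > 0) & (enc[j] > 0)
        diff = valid & (enc[i] != enc[j])
        valids[k] = valid.reshape(ncod, 3).sum(axis=1)
        diffs[k] = diff.reshape(ncod, 3).sum(axis=1)
    return valids, diffs, pairs


def _distance_matrix(
    n: int, pairs, valids: np.ndarray, diffs: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    compared = valids @ weights
    differing = diffs @ weights
    D = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(compared > 0, differing / np.maximum(compared, 1), 1.0)
    for k, (i, j) in enumerate(pairs):
        pk = p[k]
        if pk >= 0.75 or compared[k] == 0:
            d = JC_MAX_DISTANCE
        else:
            d = -0.75 * np.log1p(-(4.0 / 3.0) * pk)
        D[i, j] = D[j, i] = d
    return D


def jc_distance_matrix(alignment: MultipleAlignment) -> tuple[np.ndarray, tuple[str, ...]]:
    """JC-corrected pairwise distance matrix over the alignment's taxa."""
    enc = _encode(alignment)
    valids, diffs, pairs = _pair_stats_per_codon(enc)
    w = np.ones(valids.shape[1])
    return _distance_matrix(len(alignment.taxa), pairs, valids, diffs, w), alignment.taxa


# ---------------------------------------------------------------------------
# Neighbor joining

class _Cluster:
    __slots__ = ("leaves", "newick", "rep")

    def __init__(self, leaves: frozenset[str], newick: str):
        self.leaves = leaves
        self.newick = newick
        self.rep = min(leaves)  # tie-break representative


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion go to the lexicographically smallest pair of
    cluster representatives; negative branch lengths are clamped to zero
    with the deficit moved to the sibling branch.
    """
    n = len(labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValidationError("distance matrix shape mismatch")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    clusters = [_Cluster(frozenset([l]), None) for l in labels]
    for c, l in zip(clusters, labels):
        c.newick = _quote(l)
    D = D.astype(float).copy()
    splits: set[frozenset[str]] = set()
    while len(clusters) > 3:
        m = len(clusters)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((clusters[i].rep, clusters[j].rep)))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj = max(0.0, vj + vi)
            vi = 0.0
        if vj < 0:
            vi = max(0.0, vi + vj)
            vj = 0.0
        new_leaves = clusters[i].leaves | clusters[j].leaves
        ci, cj = clusters[i], clusters[j]
        first, second = sorted([(ci, vi), (cj, vj)], key=lambda t: t[0].rep)
        newick = (
            f"({first[0].newick}:{first[1]:.10g},{second[0].newick}:{second[1]:.10g})"
        )
        splits.add(frozenset(new_leaves))
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        clusters = [clusters[k] for k in keep] + [_Cluster(new_leaves, newick)]
        D = D2
    # join the last three clusters at an unrooted trifurcation
    (a, b, c) = clusters
    va = max(0.0, 0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    vb = max(0.0, 0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    vc = max(0.0, 0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    parts = sorted(zip((a, b, c), (va, vb, vc)), key=lambda t: t[0].rep)
    newick = (
        "(" + ",".join(f"{cl.newick}:{v:.10g}" for cl, v in parts) + ");"
    )
    for cl in (a, b, c):
        if len(cl.leaves) > 1:
            splits.add(frozenset(cl.leaves))
    taxa = tuple(sorted(labels))
    full = frozenset(taxa)
    anchor = min(taxa)
    canon = set()
    for s in splits:
        side = full - s if anchor in s else s
        if 2 <= len(side) <= len(taxa) - 2:  # nontrivial bipartitions only
            canon.add(frozenset(side))
    return PhyloTree(newick=newick, taxa=taxa, splits=frozenset(canon))


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_supports(
    alignment: MultipleAlignment, n_replicates: int, seed: int
) -> PhyloTree:
    """NJ tree with codon-column bootstrap supports.

    Codon columns (not nucleotide columns) are resampled with replacement,
    respecting the codon threading.  The support of a bipartition is the
    percent of replicate NJ trees containing it.  If the alignment has no
    variable codon columns the supports carry no signal and are flagged
    (``uninformative=True``, supports None) rather than reported as 100.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    enc = _encode(alignment)
    n = len(alignment.taxa)
    valids, diffs, pairs = _pair_stats_per_codon(enc)
    ncod = valids.shape[1]
    w_full = np.ones(ncod)
    D = _distance_matrix(n, pairs, valids, diffs, w_full)
    main = nj_tree(D, alignment.taxa)
    if diffs.sum() == 0:
        main.uninformative = True
        main.split_supports = {s: None for s in main.splits}
        return main
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in main.splits}
    for _ in range(n_replicates):
        idx = rng.integers(0, ncod, size=ncod)
        w = np.bincount(idx, minlength=ncod).astype(float)
        Db = _distance_matrix(n, pairs, valids, diffs, w)
        rep = nj_tree(Db, alignment.taxa)
        for s in rep.splits:
            if s in counts:
                counts[s] += 1
    main.split_supports = {
        s: 100.0 * c / n_replicates for s, c in counts.items()
    }
    return main


# ---------------------------------------------------------------------------
# Origin classification

def _parse_class(label: str) -> str:
    parts = label.split("|")
    return parts[1] if len(parts) >= 2 else "?"


def _rooted_tree(newick: str, outgroup: Sequence[str], taxa: Sequence[str]) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    present = {lf.taxon.label for lf in t.leaf_node_iter()}
    missing = set(outgroup) - present
    if missing:
        raise ValidationError(f"outgroup taxa absent from tree: {sorted(missing)}")
    t.is_rooted = True
    og_leaf = t.find_node_with_taxon_label(list(outgroup)[0])
    if og_leaf.edge.length is None:
        og_leaf.edge.length = 0.0
    t.reroot_at_edge(og_leaf.edge, update_bipartitions=False)
    ingroup = sorted(present - set(outgroup))
    if ingroup:
        m = t.mrca(taxon_labels=ingroup)
        if m is not None and m.parent_node is not None:
            if m.edge.length is None:
                m.edge.length = 0.0
            t.reroot_at_edge(m.edge, update_bipartitions=False)
    return t


def classify_origin(
    tree: PhyloTree,
    family: str,
    outgroup_taxa: Sequence[str],
    config: AnalysisConfig,
    autosomal_labels: Optional[Sequence[str]] = None,
) -> OriginCall:
    """Call the parental origin (X/Y/unresolved) of autosomal copies.

    The tree is rooted on the declared outgroup; the autosomal copies must
    form a clade whose sister consists solely of Y copies (verdict Y) or
    solely of X copies (verdict X), with bootstrap support of the uniting
    clade at least ``bootstrap_support_min``; otherwise unresolved.
    Invariant to taxon input order.
    """
    if autosomal_labels is None:
        autosomal_labels = [l for l in tree.taxa if _parse_class(l) == "A"]
    a_set = frozenset(autosomal_labels)
    if not a_set:
        raise ValidationError("no autosomal copies to classify")
    if not any(_parse_class(l) == "X" for l in tree.taxa):
        raise ValidationError("tree contains no X-linked copy")
    t = _rooted_tree(tree.newick, outgroup_taxa, tree.taxa)
    a_in_tree = a_set & {lf.taxon.label for lf in t.leaf_node_iter()}
    if not a_in_tree:
        raise ValidationError("autosomal labels absent from tree")
    if len(a_in_tree) == 1:
        node = t.find_node_with_taxon_label(list(a_in_tree)[0])
    else:
        node = t.mrca(taxon_labels=sorted(a_in_tree))
    clade_leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
    unresolved = OriginCall(
        family=family,
        clade=a_set,
        verdict="unresolved",
        support=None,
        sister_taxa=frozenset(),
    )
    if clade_leaves != a_in_tree:
        return unresolved  # candidates not monophyletic w.r.t. other copies
    parent = node.parent_node
    if parent is None:
        return unresolved
    sister = frozenset(
        lf.taxon.label for lf in parent.leaf_iter()
    ) - clade_leaves
    if not sister:
        return unresolved
    classes = {_parse_class(l) for l in sister}
    if classes == {"Y"}:
        verdict = "Y"
    elif classes == {"X"}:
        verdict = "X"
    else:
        return unresolved
    support = tree.support_for(clade_leaves | sister)
    if support is None or support < config.bootstrap_support_min:
        return OriginCall(
            family=family,
            clade=a_set,
            verdict="unresolved",
            support=support,
            sister_taxa=sister,
        )
    return OriginCall(
        family=family,
        clade=a_set,
        verdict=verdict,
        support=support,
        sister_taxa=sister,
    )
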