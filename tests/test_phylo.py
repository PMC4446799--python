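"""Neighbor joining, bootstrap supports, and parental-origin calls."""

import numpy as np
import pytest

from yrescue import simulate as sim
from yrescue.align import align_codons
from yrescue.phylo import bootstrap_supports, classify_origin, nj_tree
from yrescue.types import AnalysisConfig, GeneCopy, ValidationError


def random_additive_tree(n, rng):
    """Random unrooted binary tree with positive branch lengths; returns
    (splits, leaf-to-leaf distance matrix)."""
    labels = [f"t{i}" for i in range(n)]
    # grow by attaching each new leaf to a uniformly chosen existing edge
    # distances maintained directly (additivity by construction)
    import itertools

    nodes = {0: {}, 1: {}}
    edges = {}

    def add_edge(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w
        nodes[u][v] = w
        nodes[v][u] = w

    add_edge(0, 1, float(rng.uniform(0.1, 1.0)))
    leaf_ids = {0: "t0", 1: "t1"}
    next_id = 2
    for i in range(2, n):
        u, v = list(edges.keys())[int(rng.integers(0, len(edges)))]
        w = nodes[u].pop(v)
        nodes[v].pop(u)
        edges.pop((u, v))
        edges.pop((v, u))
        mid = next_id
        next_id += 1
        nodes[mid] = {}
        f = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * f)
        add_edge(mid, v, w * (1 - f))
        leaf = next_id
        next_id += 1
        nodes[leaf] = {}
        add_edge(mid, leaf, float(rng.uniform(0.1, 1.0)))
        leaf_ids[leaf] = f"t{i}"

    # all-pairs distances by DFS
    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in nodes[x].items():
                if y not in out:
                    out[y] = out[x] + w
                    stack.append(y)
        return out

    leaf_nodes = sorted(leaf_ids, key=lambda k: leaf_ids[k])
    labels = [leaf_ids[k] for k in leaf_nodes]
    D = np.zeros((n, n))
    for i, u in enumerate(leaf_nodes):
        du = dists_from(u)
        for j, v in enumerate(leaf_nodes):
            D[i, j] = du[v]

    # true splits: remove each internal edge, collect leaf side
    full = frozenset(labels)
    anchor = min(labels)
    splits = set()
    for (u, v) in {tuple(sorted(e)) for e in edges}:
        seen = {u}
        stack = [u]
        blocked = {v}
        while stack:
            x = stack.pop()
            for y in nodes[x]:
                if y not in seen and y not in blocked:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(leaf_ids[k] for k in seen if k in leaf_ids)
        if 2 <= len(side) <= n - 2:
            splits.add(side if anchor not in side else full - side)
    return labels, D, splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        t = nj_tree(D, ["a", "b", "c"])
        # v_a = (5+9-10)/2 = 2, v_b = 3, v_c = 7
        assert "a:2" in t.newick and "b:3" in t.newick and "c:7" in t.newick

    def test_four_taxa_additive_recovery(self):
        # tree ((a,b),(c,d)) with internal edge 2
        D = np.array(
            [[0, 3, 6, 7], [3, 0, 7, 8], [6, 7, 0, 7], [7, 8, 7, 0]], float
        )
        t = nj_tree(D, ["a", "b", "c", "d"])
        assert frozenset({"c", "d"}) in t.splits

    def test_random_additive_trees_recovered(self, rng):
        """NJ is consistent on additive matrices (up to 8 taxa)."""
        for _ in range(25):
            n = int(rng.integers(4, 9))
            labels, D, true_splits = random_additive_tree(n, rng)
            t = nj_tree(D, labels)
            assert t.splits == frozenset(true_splits)

    def test_degenerate_equal_distances_deterministic(self):
        D = np.ones((5, 5)) - np.eye(5)
        labels = [f"t{i}" for i in range(5)]
        t1 = nj_tree(D.copy(), labels)
        t2 = nj_tree(D.copy(), labels)
        assert t1.newick == t2.newick

    def test_too_few_taxa(self):
        with pytest.raises(ValidationError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])


def _family_alignment(seed=5, subs_rate=0.004):
    """Simulated family on the packaged tree, aligned."""
    from yrescue.fixtures import curated_tree

    tree = curated_tree()
    cfg = sim.SimConfig(tree=tree, seed=seed, subs_rate=subs_rate)
    cfg.event_specs = [sim.EventSpec("FAM1", "Y", "cattle")]
    copies, _, _, _ = sim.simulate_family(cfg, "FAM1")
    return align_codons([c for c in copies if c.cds])


class TestBootstrap:
    def test_identical_sequences_flagged_uninformative(self):
        cds = "ATGAAACCCGGGTTTAAG" * 10
        copies = [
            GeneCopy("F", s, "X", "l", cds=cds) for s in ("s1", "s2", "s3", "s4")
        ]
        t = bootstrap_supports(align_codons(copies), 25, seed=1)
        assert t.uninformative
        assert all(v is None for v in t.split_supports.values())

    def test_deep_split_strongly_supported(self):
        aln = _family_alignment()
        t = bootstrap_supports(aln, 100, seed=2)
        # X copies and Y copies diverged long ago: the X clade should be a
        # strongly supported split
        x_side = frozenset(l for l in t.taxa if "|X|" in l)
        support = t.support_for(x_side)
        assert support is not None and support >= 95

    def test_same_seed_identical_supports(self):
        aln = _family_alignment()
        t1 = bootstrap_supports(aln, 50, seed=9)
        t2 = bootstrap_supports(aln, 50, seed=9)
        assert t1.split_supports == t2.split_supports
        t3 = bootstrap_supports(aln, 50, seed=10)
        assert t1.newick == t3.newick  # point estimate independent of seed


class TestClassifyOrigin:
    def _tree_and_labels(self, seed=5):
        aln = _family_alignment(seed=seed)
        t = bootstrap_supports(aln, 100, seed=seed)
        a_labels = [l for l in t.taxa if "|A|" in l]
        out = [l for l in t.taxa if l.startswith(("opossum|X", "wallaby|X"))]
        return t, a_labels, out

    def test_y_derived_copy_called_y(self, config):
        t, a_labels, out = self._tree_and_labels()
        call = classify_origin(t, "FAM1", out, config, autosomal_labels=a_labels)
        assert call.verdict == "Y"
        assert call.support >= config.bootstrap_support_min
        assert all("|Y|" in l for l in call.sister_taxa)

    def test_taxon_order_invariance(self, config):
        t, a_labels, out = self._tree_and_labels()
        call1 = classify_origin(t, "FAM1", out, config, autosomal_labels=a_labels)
        call2 = classify_origin(
            t, "FAM1", list(reversed(out)), config, autosomal_labels=list(reversed(a_labels))
        )
        assert (call1.verdict, call1.support) == (call2.verdict, call2.support)

    def test_missing_outgroup_errors(self, config):
        t, a_labels, _ = self._tree_and_labels()
        with pytest.raises(ValidationError, match="outgroup"):
            classify_origin(t, "FAM1", ["nosuch|X|l"], config, autosomal_labels=a_labels)

    def test_origin_recovery_rate(self, config):
        """Planted Y-derived retrocopies are called Y in >= 95% of seeded
        replicates when the gametolog split is deep and the shared branch
        with the true parent is long."""
        ok = 0
        n = 12
        for seed in range(n):
            t, a_labels, out = self._tree_and_labels(seed=100 + seed)
            call = classify_origin(t, "FAM1", out, config, autosomal_labels=a_labels)
            ok += call.verdict == "Y"
        assert ok >= n - 1
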