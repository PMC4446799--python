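"""Dollo parsimony placement and rescue calling."""

from itertools import combinations

import pytest

from yrescue import simulate as sim
from yrescue.rescue import call_rescues, dollo_gains, dollo_losses
from yrescue.tree import species_tree_from_newick
from yrescue.types import AnalysisConfig, ValidationError


# ---------------------------------------------------------------------------
# helpers: exhaustive topology enumeration + brute-force minimal loss sets

def all_rooted_topologies(labels):
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for k in range(len(rest) + 1):
        for extra in combinations(rest, k):
            left = (first,) + extra
            right = tuple(l for l in rest if l not in extra)
            if not right:
                continue
            for t1 in all_rooted_topologies(left):
                for t2 in all_rooted_topologies(right):
                    yield (t1, t2)


def to_ultrametric_newick(top):
    def height(t):
        return 0 if isinstance(t, str) else 1 + max(height(t[0]), height(t[1]))

    h = height(top)

    def emit(t, parent_h):
        th = height(t)
        label = t if isinstance(t, str) else f"({emit(t[0], th)},{emit(t[1], th)})"
        return f"{label}:{parent_h - th}"

    if isinstance(top, str):
        return f"{top}:0;"
    return f"({emit(top[0], h)},{emit(top[1], h)});"


def node_leafsets(top):
    out = []

    def walk(t):
        if isinstance(t, str):
            out.append(frozenset([t]))
            return frozenset([t])
        s = walk(t[0]) | walk(t[1])
        out.append(s)
        return s

    walk(top)
    return out


def brute_force_min_losses(top, absent):
    """Smallest set of branches whose subtree-leaf union equals ``absent``."""
    sets = [s for s in node_leafsets(top) if s <= absent]
    for k in range(0, len(sets) + 1):
        for combo in combinations(sets, k):
            union = frozenset().union(*combo) if combo else frozenset()
            if union == absent:
                return k
    return None


class TestDolloLosses:
    def test_rodent_only_absence_is_one_stem_loss(self, curated, tree):
        hom = curated[0]
        scope = hom.family_scope("EIF1A")
        sub = tree.restrict_to(scope)
        presence = {s: hom.presence("EIF1A", s, "Y") for s in scope}
        losses = dollo_losses(sub, "EIF1A", presence)
        assert len(losses) == 1
        assert losses[0].affected_species == frozenset({"mouse", "rat"})

    def test_present_everywhere_no_losses(self, tree):
        presence = {s: True for s in tree.leaf_labels}
        assert dollo_losses(tree, "F", presence) == []

    def test_absent_everywhere_errors(self, tree):
        presence = {s: False for s in tree.leaf_labels}
        with pytest.raises(ValidationError, match="origin"):
            dollo_losses(tree, "F", presence)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_matches_brute_force_on_all_small_trees(self, n):
        """Loss placement is minimal for every topology and every
        presence pattern on small trees."""
        labels = tuple(f"s{i}" for i in range(n))
        for top in all_rooted_topologies(labels):
            st = species_tree_from_newick(to_ultrametric_newick(top))
            for mask in range(1, 2**n - 1):
                absent = frozenset(l for i, l in enumerate(labels) if mask >> i & 1)
                presence = {l: l not in absent for l in labels}
                losses = dollo_losses(st, "F", presence)
                union = frozenset().union(*(l.affected_species for l in losses)) if losses else frozenset()
                assert union == absent
                assert len(losses) == brute_force_min_losses(top, absent)


class TestDolloGains:
    def test_three_primate_groups_three_gains(self, curated, config):
        from yrescue.synteny import locus_groups

        hom, tree, syn, _ = curated
        primates = [r for r in syn if r.family == "EIF2S3" and r.species != "cattle"]
        groups = locus_groups(primates, config)
        gains = dollo_gains(tree, "EIF2S3", groups)
        assert len(gains) == 3

    def test_rodent_group_single_gain_on_stem(self, tree):
        gains = dollo_gains(tree, "EIF1A", [frozenset({("mouse", "l"), ("rat", "l")})])
        assert len(gains) == 1
        assert gains[0].branch_id == "mouse+rat"

    def test_same_branch_loci_collapse(self, tree):
        """Two marsupial loci on the same stem collapse to one gain that
        still reports both loci."""
        g1 = frozenset({("opossum", "l1"), ("wallaby", "l1")})
        g2 = frozenset({("opossum", "l2"), ("wallaby", "l2")})
        gains = dollo_gains(tree, "RPS4", [g1, g2])
        assert len(gains) == 1
        assert gains[0].n_loci == 2


class TestCallRescues:
    def test_planted_rescues_and_pseudogene(self, tree, config):
        """Two planted rescues and one planted pseudogene: exactly the two
        real events are called."""
        rodent = tree.branch_id(tree.mrca(["mouse", "rat"]))
        marsup = tree.branch_id(tree.mrca(["opossum", "wallaby"]))
        cfg = sim.SimConfig(tree=tree, seed=12)
        cfg.event_specs = [
            sim.EventSpec("FAM1", "Y", rodent),
            sim.EventSpec("FAM2", "X", marsup),
            sim.EventSpec("FAM3", "Y", "cattle", pseudogenize=True),
        ]
        cfg.loss_specs = [("FAM1", rodent), ("FAM2", marsup), ("FAM3", "cattle")]
        from yrescue import run_pipeline
        from yrescue.types import HomologTable

        copies, syn, truth = [], [], {}
        for fam in ("FAM1", "FAM2", "FAM3"):
            c, s, _, _ = sim.simulate_family(cfg, fam)
            copies += c
            syn += s
        hom = HomologTable(copies)
        reads, _ = sim.simulate_reads(
            copies, {}, depth=60, read_length=75, error_rate=0.002, seed=13,
        )
        res = run_pipeline(hom, tree, reads=reads, synteny_records=syn, config=config)
        assert res.report.n_rescues() == 2
        assert sorted(r.family for r in res.report.rescues) == ["FAM1", "FAM2"]
        excluded = {g.family: reason for g, reason in res.report.excluded_gains}
        assert "FAM3" in excluded and "pseudogene" in excluded["FAM3"]

    def test_report_bytes_deterministic(self, curated, config):
        from yrescue import run_pipeline

        hom, tree, syn, ev = curated
        r1 = run_pipeline(hom, tree, synteny_records=syn, curated_evidence=ev, config=config)
        r2 = run_pipeline(hom, tree, synteny_records=syn, curated_evidence=ev, config=config)
        assert r1.report.to_json() == r2.report.to_json()
        assert r1.report.to_tsv() == r2.report.to_tsv()
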