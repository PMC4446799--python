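"""Read assignment, expression ratios and pattern calls."""

import numpy as np
import pytest

from yrescue import simulate as sim
from yrescue.expression import (
    ExpressionProfile,
    assign_reads,
    build_profile,
    classify_pattern,
    expression_ratio,
    has_transcription_evidence,
    revcomp,
)
from yrescue.types import AnalysisConfig, GeneCopy, Read, ReadSet, ValidationError


def _copy(species, cc, locus, cds):
    mech = "retro" if cc == "A" else "unknown"
    return GeneCopy("FAM", species, cc, locus, cds=cds, mechanism_hint=mech)


def _readset(seqs, tissue="testis", species="mouse"):
    reads = [Read(f"r{i}", s, tissue, species) for i, s in enumerate(seqs)]
    return ReadSet(reads=reads, read_length=max(len(s) for s in seqs))


@pytest.fixture()
def homolog_pair(rng):
    """An A and an X copy, ~5% diverged."""
    base = sim.random_cds(220, rng)
    core = base[3:-3]
    a_core, _ = sim.evolve_codon_sequence(core, 0.025, 1.0, rng)
    x_core, _ = sim.evolve_codon_sequence(core, 0.025, 1.0, rng)
    a = _copy("mouse", "A", "locA", "ATG" + a_core + "TAA")
    x = _copy("mouse", "X", "locX", "ATG" + x_core + "TAA")
    return a, x


class TestAssignReads:
    def test_exact_match_assigned_at_discriminating_site(self, homolog_pair):
        a, x = homolog_pair
        # find a window where the two copies differ
        start = next(
            i for i in range(0, len(a.cds) - 75)
            if a.cds[i : i + 75] != x.cds[i : i + 75]
        )
        rs = _readset([a.cds[start : start + 75]])
        res = assign_reads(rs, [a, x])
        assert res.counts[a.label].get("testis", 0) == 1

    def test_identical_region_is_ambiguous(self):
        shared = "ATG" + "AAACCCGGGTTT" * 10
        a = _copy("mouse", "A", "locA", shared + "CATTCCGCA" * 8 + "TAA")
        x = _copy("mouse", "X", "locX", shared + "GGGCGCAAT" * 8 + "TAA")
        rs = _readset([shared[:60]])
        res = assign_reads(rs, [a, x])
        assert res.ambiguous.get("testis", 0) == 1

    def test_reverse_strand_reads_assigned(self, homolog_pair):
        a, x = homolog_pair
        start = next(
            i for i in range(0, len(a.cds) - 75)
            if a.cds[i : i + 75] != x.cds[i : i + 75]
        )
        rs = _readset([revcomp(a.cds[start : start + 75])])
        res = assign_reads(rs, [a, x])
        assert res.counts[a.label].get("testis", 0) == 1

    def test_counts_partition_totals(self, homolog_pair, rng):
        a, x = homolog_pair
        reads, _ = sim.simulate_reads(
            [a, x], {}, depth=100, read_length=75, error_rate=0.01, seed=3,
            tissue_panel=("brain", "testis"),
        )
        rs = reads["mouse"]
        res = assign_reads(rs, [a, x])
        for tissue, total in res.total.items():
            assigned = sum(res.counts[l].get(tissue, 0) for l in res.counts)
            assert assigned + res.ambiguous.get(tissue, 0) + res.unassigned.get(tissue, 0) == total

    def test_accuracy_on_noisy_reads(self, homolog_pair):
        """>= 90% of non-ambiguous reads from 5%-diverged copies are
        correctly assigned at 1% sequencing error."""
        a, x = homolog_pair
        reads, truth = sim.simulate_reads(
            [a, x], {}, depth=400, read_length=75, error_rate=0.01, seed=4,
            tissue_panel=("testis",),
        )
        rs = reads["mouse"]
        res = assign_reads(rs, [a, x])
        correct = wrong = 0
        for rid, label in res.assigned_labels.items():
            if truth.read_origin[("mouse", rid)] == label:
                correct += 1
            else:
                wrong += 1
        assert correct / (correct + wrong) >= 0.90

    def test_empty_homologs_error(self):
        with pytest.raises(ValidationError):
            assign_reads(_readset(["ACGT" * 20]), [])


class TestExpressionRatio:
    @pytest.mark.parametrize(
        "ca,la,cx,lx,expected",
        [(100, 1000, 100, 1000, 1.0), (50, 500, 100, 1000, 1.0), (0, 1000, 100, 1000, 0.0)],
    )
    def test_arithmetic(self, ca, la, cx, lx, expected):
        assert expression_ratio(ca, la, cx, lx) == pytest.approx(expected)

    def test_zero_x_is_undefined(self):
        assert expression_ratio(10, 1000, 0, 1000) is None

    def test_scale_invariance(self, rng):
        for _ in range(20):
            ca, cx = rng.integers(1, 1000, size=2)
            la, lx = rng.integers(100, 3000, size=2)
            c = float(rng.uniform(0.1, 50))
            r1 = expression_ratio(ca, la, cx, lx)
            r2 = expression_ratio(c * ca, la, c * cx, lx)
            assert r2 == pytest.approx(r1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            expression_ratio(-1, 1000, 10, 1000)


def _profile(counts, length=1000):
    cds = "ATG" + "AAA" * ((length - 6) // 3) + "TAA"
    copy = _copy("mouse", "A", "locA", cds)
    norm = {t: c / (len(cds) / 1000) for t, c in counts.items()}
    return ExpressionProfile(copy=copy, counts=counts, normalized=norm, ratio_vs_x={})


PANEL = ("brain", "heart", "kidney", "liver", "testis")


class TestTranscriptionAndPattern:
    def test_all_zero_is_silent_and_untranscribed(self, config):
        p = _profile({t: 0 for t in PANEL})
        assert not has_transcription_evidence(p, config)
        assert classify_pattern(p, PANEL, config) == ("silent", 0)

    def test_threshold_boundary_inclusive(self, config):
        p = _profile({"testis": 10, **{t: 0 for t in PANEL if t != "testis"}})
        assert has_transcription_evidence(p, config)

    def test_below_threshold_everywhere_is_false(self, config):
        p = _profile({t: 9 for t in PANEL})
        assert not has_transcription_evidence(p, config)

    def test_equal_five_tissues_is_broad(self, config):
        p = _profile({t: 50 for t in PANEL})
        assert classify_pattern(p, PANEL, config) == ("broad", 5)

    def test_testis_fold_is_specific(self, config):
        p = _profile({"testis": 200, **{t: 20 for t in PANEL if t != "testis"}})
        pattern, breadth = classify_pattern(p, PANEL, config)
        assert pattern == "testis_specific"

    def test_panel_without_testis_errors(self, config):
        p = _profile({"brain": 10})
        with pytest.raises(ValidationError):
            classify_pattern(p, ("brain",), config)

    def test_simulated_testis_predominant_profile(self, homolog_pair, config):
        a, x = homolog_pair
        reads, _ = sim.simulate_reads(
            [a, x], {a.label: ("testis_specific", 10.0)},
            depth=300, read_length=75, error_rate=0.002, seed=6, tissue_panel=PANEL,
        )
        res = assign_reads(reads["mouse"], [a, x])
        profile = build_profile(a, res, PANEL, config, x)
        assert profile.pattern == "testis_specific"

    def test_recovered_ratio_within_fifteen_percent(self, homolog_pair, config):
        """The A:X ratio recovers the simulated 1:1 truth within 15% when
        both copies get >= 500 non-ambiguous reads."""
        a, x = homolog_pair
        reads, _ = sim.simulate_reads(
            [a, x], {}, depth=900, read_length=75, error_rate=0.002, seed=7,
            tissue_panel=("testis",),
        )
        res = assign_reads(reads["mouse"], [a, x])
        assert res.counts[a.label]["testis"] >= 500
        assert res.counts[x.label]["testis"] >= 500
        profile = build_profile(a, res, ("testis",), config, x)
        assert profile.ratio_vs_x["testis"] == pytest.approx(1.0, rel=0.15)
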