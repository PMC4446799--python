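"""Divergence, the recency filter, and NG86 dN/dS against an independent
exhaustive oracle."""

import math
from itertools import product

import numpy as np
import pytest

from yrescue.divergence import (
    DivergenceResult,
    jukes_cantor,
    ng86_dnds,
    p_distance,
    recency_filter,
)
from yrescue.orf import STOP_CODONS, translate_codon
from yrescue.types import AnalysisConfig, ValidationError

SENSE = [
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
]


# ---------------------------------------------------------------------------
# Independent oracle: recursive path enumeration over the codon graph

def oracle_codon_sites(codon):
    """Site fractions by direct enumeration of the 9 single-base mutants."""
    syn = 0.0
    for pos in range(3):
        muts = [
            codon[:pos] + b + codon[pos + 1 :]
            for b in "ACGT"
            if b != codon[pos]
        ]
        valid = [m for m in muts if m not in STOP_CODONS]
        syn += sum(translate_codon(m) == translate_codon(codon) for m in valid) / len(valid)
    return syn, 3.0 - syn


def oracle_pair_diffs(ca, cb):
    """Average syn/nonsyn steps over all stop-free shortest paths, found by
    recursive depth-first enumeration (independent of the permutation-based
    implementation)."""
    paths = []

    def explore(cur, syn, nonsyn):
        if cur == cb:
            paths.append((syn, nonsyn))
            return
        for pos in range(3):
            if cur[pos] != cb[pos]:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS:
                    continue
                if translate_codon(nxt) == translate_codon(cur):
                    explore(nxt, syn + 1, nonsyn)
                else:
                    explore(nxt, syn, nonsyn + 1)

    explore(ca, 0, 0)
    if not paths:
        return None
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_dnds_counts(a, b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        d = oracle_pair_diffs(ca, cb)
        if d is None:
            continue
        sa, na = oracle_codon_sites(ca)
        sb, nb = oracle_codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += d[0]
        Nd += d[1]
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------

class TestPDistance:
    def test_identical(self):
        d = p_distance("A" * 100, "A" * 100)
        assert d.p_distance == 0 and d.jc_distance == 0

    def test_jc_closed_form(self):
        d = p_distance("A" * 90 + "C" * 10, "A" * 100)
        assert d.p_distance == pytest.approx(0.1)
        assert d.jc_distance == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert d.jc_distance == pytest.approx(0.10732, abs=1e-5)

    def test_one_diff_in_hundred(self):
        d = p_distance("A" * 99 + "C", "A" * 100)
        assert d.p_distance == pytest.approx(0.01)

    def test_gap_and_n_columns_excluded(self):
        d = p_distance("AC-NTT", "ACGGTA")
        assert d.compared_sites == 4
        assert d.differing_sites == 1

    def test_saturated_jc_undefined(self):
        d = p_distance("A" * 100, "C" * 80 + "A" * 20)
        assert d.p_distance == pytest.approx(0.8)
        assert d.jc_distance is None

    def test_no_comparable_columns(self):
        with pytest.raises(ValidationError):
            p_distance("NNN", "AAA")

    def test_jc_geq_p_whenever_defined(self, rng):
        for _ in range(50):
            p = float(rng.uniform(0, 0.74))
            assert jukes_cantor(p) >= p - 1e-12


class TestRecencyFilter:
    @pytest.mark.parametrize(
        "p,expected", [(0.019, "dismiss"), (0.020, "keep"), (0.05, "keep")]
    )
    def test_strict_threshold(self, p, expected, config):
        div = DivergenceResult(1000, int(p * 1000), p, jukes_cantor(p))
        assert recency_filter(div, config) == expected


class TestNg86:
    def test_single_synonymous_difference(self):
        r = ng86_dnds("TTTAAA", "TTCAAA")
        assert r.Sd == pytest.approx(1.0)
        assert r.Nd == pytest.approx(0.0)
        assert r.dN == pytest.approx(0.0)
        assert r.omega == pytest.approx(0.0)

    def test_identical_sequences_omega_undefined(self):
        r = ng86_dnds("TTTAAA", "TTTAAA")
        assert r.dN == 0 and r.dS == 0
        assert r.omega is None

    def test_in_frame_stop_rejected(self):
        with pytest.raises(ValidationError, match="stop"):
            ng86_dnds("TAAAAA", "TTTAAA")

    def test_symmetry_exact(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(SENSE, size=10))
            b = "".join(rng.choice(SENSE, size=10))
            ra, rb = ng86_dnds(a, b), ng86_dnds(b, a)
            assert (ra.Sd, ra.Nd, ra.S_sites, ra.N_sites) == (rb.Sd, rb.Nd, rb.S_sites, rb.N_sites)

    def test_site_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            a = "".join(rng.choice(SENSE, size=n))
            b = "".join(rng.choice(SENSE, size=n))
            r = ng86_dnds(a, b)
            assert r.S_sites + r.N_sites == pytest.approx(3 * r.compared_codons, abs=1e-9)

    def test_n_codons_excluded(self):
        r = ng86_dnds("TTTNNAAAA", "TTCAGAAAA")
        assert r.compared_codons == 2  # middle codon dropped

    def test_matches_exhaustive_oracle(self, rng):
        """Sd/Nd/S/N agree with independent path enumeration to 1e-12."""
        for _ in range(300):
            n = int(rng.integers(1, 6))
            a = "".join(rng.choice(SENSE, size=n))
            b = "".join(rng.choice(SENSE, size=n))
            r = ng86_dnds(a, b)
            S, N, Sd, Nd = oracle_dnds_counts(a, b)
            assert r.Sd == pytest.approx(Sd, abs=1e-12)
            assert r.Nd == pytest.approx(Nd, abs=1e-12)
            assert r.S_sites == pytest.approx(S, abs=1e-12)
            assert r.N_sites == pytest.approx(N, abs=1e-12)
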