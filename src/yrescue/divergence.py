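"""Pairwise divergence and counting-method dN/dS.

Two quantities feed the rescue evidence bundle:

* uncorrected nucleotide divergence (p-distance) between a transposed copy
  and its parental copy — copies under 2% diverged are dismissed as too
  recent to have been vetted by selection;
* the dN/dS ratio (omega) between carriers of the same transposed locus,
  computed with the Nei–Gojobori (1986) counting method and Jukes–Cantor
  correction — omega << 1 is the signature of purifying selection, i.e. of
  a functional gene.

NG86 conventions used here: per-codon synonymous site fractions enumerate
the 9 single-base mutations with mutations to stop codons removed from the
denominator (each codon still contributes exactly 3 sites); differences
between codons are averaged over all shortest substitution pathways that
avoid stop-codon intermediates, with equal pathway weighting.  Codon pairs
whose pathways all cross a stop are skipped (with a warning) and excluded
from the site totals.  Codons containing N or a gap in either sequence are
excluded throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

from .orf import STOP_CODONS, translate_codon
from .types import AnalysisConfig, ValidationError

log = logging.getLogger("yrescue.divergence")

BASES = "ACGT"


@dataclass(frozen=True)
class DivergenceResult:
    compared_sites: int
    differing_sites: int
    p_distance: float
    jc_distance: Optional[float]  # None when p >= 0.75 (JC undefined)


@dataclass(frozen=True)
class DndsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]  # None iff dS == 0 or undefined
    compared_codons: int = 0


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance −(3/4)·ln(1 − (4/3)p); None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def p_distance(aligned_a: str, aligned_b: str) -> DivergenceResult:
    """Uncorrected divergence over columns free of gaps and N in both rows."""
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned sequences differ in length")
    a = aligned_a.upper()
    b = aligned_b.upper()
    compared = 0
    diff = 0
    for ca, cb in zip(a, b):
        if ca in "-N" or cb in "-N":
            continue
        compared += 1
        if ca != cb:
            diff += 1
    if compared == 0:
        raise ValidationError("no comparable (gap/N-free) columns")
    p = diff / compared
    return DivergenceResult(
        compared_sites=compared,
        differing_sites=diff,
        p_distance=p,
        jc_distance=jukes_cantor(p),
    )


def recency_filter(div: DivergenceResult, config: AnalysisConfig) -> str:
    """'dismiss' iff strictly under the recency threshold, else 'keep'."""
    return "dismiss" if div.p_distance < config.recency_threshold else "keep"


# ---------------------------------------------------------------------------
# NG86

def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Position by position, the fraction of the site that is synonymous is
    (# synonymous single-base changes) / (# changes not creating a stop);
    each position contributes one full site, so the pair sums to 3.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_valid += 1
            if translate_codon(mutant) == aa:
                n_syn += 1
        syn += n_syn / n_valid  # n_valid >= 1 for every sense codon
    return syn, 3.0 - syn


def _codon_pair_differences(codon_a: str, codon_b: str) -> Optional[tuple[float, float]]:
    """Average (synonymous, nonsynonymous) difference counts over all
    shortest substitution pathways between two sense codons that avoid
    stop-codon intermediates.  None if every pathway crosses a stop.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        syn = 0.0
        nonsyn = 0.0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            syn_total += syn
            nonsyn_total += nonsyn
            n_paths += 1
    if n_paths == 0:
        return None
    return syn_total / n_paths, nonsyn_total / n_paths


def _iter_codon_pairs(a: str, b: str):
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        yield i // 3, ca, cb


def ng86_dnds(codon_aligned_a: str, codon_aligned_b: str) -> DndsResult:
    """Nei–Gojobori (1986) dN/dS for a codon-aligned sequence pair.

    Preconditions: equal lengths divisible by 3 and no in-frame stop codons
    (strip terminal stops first).  Symmetric in its arguments.
    """
    a = codon_aligned_a.upper()
    b = codon_aligned_b.upper()
    if len(a) != len(b):
        raise ValidationError("sequences differ in length")
    if len(a) % 3 != 0:
        raise ValidationError("aligned length not divisible by 3")
    for name, seq in (("a", a), ("b", b)):
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "-" in codon or "N" in codon:
                continue
            if codon in STOP_CODONS:
                raise ValidationError(
                    f"in-frame stop codon in sequence {name} at codon {i // 3}"
                )
    S = N = Sd = Nd = 0.0
    compared = 0
    for idx, ca, cb in _iter_codon_pairs(a, b):
        diffs = _codon_pair_differences(ca, cb)
        if diffs is None:
            log.warning(
                "codon pair %s/%s at %d has no stop-free pathway; skipped", ca, cb, idx
            )
            continue
        sa, na = _codon_site_fractions(ca)
        sb, nb = _codon_site_fractions(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += diffs[0]
        Nd += diffs[1]
        compared += 1
    if compared == 0:
        raise ValidationError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    # omega is undefined without synonymous signal (dS == 0 or saturated);
    # except that zero nonsynonymous change alongside synonymous change is
    # an unambiguous omega of 0 even when dS itself is saturated
    omega: Optional[float]
    if dN == 0.0 and Sd > 0:
        omega = 0.0
    elif dS is None or dN is None or dS == 0.0:
        omega = None
    else:
        omega = dN / dS
    return DndsResult(
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        compared_codons=compared,
    )
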