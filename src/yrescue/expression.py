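"""Paralog-aware read assignment and expression-pattern classification.

Reads are assigned to the homolog (autosomal vs X-linked vs Y-linked copy
of one family, one species) with the fewest mismatches over the best
ungapped alignment, considering both strands and all offsets; ties are
ambiguous and discarded.  Candidate (copy, strand, offset) triples are
found by a seed-and-extend scheme: a read with at most ``tolerance``
mismatches must contain an exact chunk of length floor(L/(tolerance+1))
(pigeonhole), so only seeded diagonals need scoring — reads from other
gene families fall out cheaply as unassigned.

Expression levels are length-normalized (reads per kb of CDS); the
autosomal:X ratio per tissue, the breadth (number of tissues with evidence
of expression) and the broad / testis-specific / silent pattern call
follow from the assigned counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import AnalysisConfig, GeneCopy, ReadSet, ValidationError

log = logging.getLogger("yrescue.expression")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AssignmentResult:
    counts: dict[str, dict[str, int]]      # copy label -> tissue -> reads
    ambiguous: dict[str, int]              # tissue -> reads
    unassigned: dict[str, int]             # tissue -> reads
    total: dict[str, int]                  # tissue -> reads
    assigned_labels: dict[str, str] = field(default_factory=dict)  # read id -> copy label


@dataclass
class ExpressionProfile:
    copy: GeneCopy
    counts: dict[str, int]                 # tissue -> assigned reads
    normalized: dict[str, float]           # tissue -> reads per kb of CDS
    ratio_vs_x: dict[str, Optional[float]] # tissue -> A:X ratio (None if X count 0)
    breadth: int = 0
    pattern: Optional[str] = None


def _best_hits(read: str, arrays, index, chunk: int, tol: int) -> dict[int, int]:
    """Minimum mismatch count per copy index over seeded diagonals."""
    L = len(read)
    rbytes = np.frombuffer(read.encode(), dtype=np.uint8)
    candidates: set[tuple[int, int, int]] = set()
    n_chunks = max(1, min(tol + 1, L // chunk))
    for ci in range(n_chunks):
        o = ci * chunk
        kmer = read[o : o + chunk]
        for copy_i, strand, pos in index.get(kmer, ()):
            offset = pos - o
            if offset < 0:
                continue
            candidates.add((copy_i, strand, offset))
    best: dict[int, int] = {}
    for copy_i, strand, offset in candidates:
        arr = arrays[copy_i][strand]
        if offset + L > len(arr):
            continue
        mm = int((arr[offset : offset + L] != rbytes).sum())
        if copy_i not in best or mm < best[copy_i]:
            best[copy_i] = mm
    return best


def assign_reads(
    reads: ReadSet, homologs: list[GeneCopy], mismatch_tolerance: int = 3
) -> AssignmentResult:
    """Uniquely assign reads to homologs of one family and species.

    A read is assigned to the homolog with the fewest mismatches if that
    minimum is <= ``mismatch_tolerance`` and strictly smaller than against
    every other homolog; ties are discarded as ambiguous.  Per tissue,
    assigned + ambiguous + unassigned always equals the read total.
    """
    if not homologs:
        raise ValidationError("empty homolog list")
    for h in homologs:
        if h.cds is None:
            raise ValidationError(f"homolog {h.label} has no sequence")
    species = {h.species for h in homologs}
    if len(species) > 1:
        raise ValidationError(f"homologs span several species: {sorted(species)}")
    fams = {h.family for h in homologs}
    if len(fams) > 1:
        raise ValidationError(f"homologs span several families: {sorted(fams)}")

    arrays = []
    for h in homologs:
        fwd = np.frombuffer(h.cds.encode(), dtype=np.uint8)
        rev = np.frombuffer(revcomp(h.cds).encode(), dtype=np.uint8)
        arrays.append((fwd, rev))
    read_len = max((len(r.sequence) for r in reads.reads), default=0)
    chunk = max(8, read_len // (mismatch_tolerance + 1)) if read_len else 8
    index: dict[str, list[tuple[int, int, int]]] = {}
    for copy_i, h in enumerate(homologs):
        for strand, seq in enumerate((h.cds, revcomp(h.cds))):
            for pos in range(0, len(seq) - chunk + 1):
                index.setdefault(seq[pos : pos + chunk], []).append(
                    (copy_i, strand, pos)
                )

    labels = [h.label for h in homologs]
    counts = {l: {} for l in labels}
    ambiguous: dict[str, int] = {}
    unassigned: dict[str, int] = {}
    total: dict[str, int] = {}
    assigned_labels: dict[str, str] = {}
    for r in reads.reads:
        tissue = r.tissue
        total[tissue] = total.get(tissue, 0) + 1
        best = _best_hits(r.sequence, arrays, index, chunk, mismatch_tolerance)
        if not best:
            unassigned[tissue] = unassigned.get(tissue, 0) + 1
            continue
        mmin = min(best.values())
        winners = [ci for ci, mm in best.items() if mm == mmin]
        if mmin > mismatch_tolerance:
            unassigned[tissue] = unassigned.get(tissue, 0) + 1
        elif len(winners) > 1:
            ambiguous[tissue] = ambiguous.get(tissue, 0) + 1
        else:
            label = labels[winners[0]]
            counts[label][tissue] = counts[label].get(tissue, 0) + 1
            assigned_labels[r.identifier] = label
    return AssignmentResult(
        counts=counts,
        ambiguous=ambiguous,
        unassigned=unassigned,
        total=total,
        assigned_labels=assigned_labels,
    )


def expression_ratio(
    counts_a: float, len_a: float, counts_x: float, len_x: float
) -> Optional[float]:
    """Length-normalized autosomal:X expression ratio.

    (counts_a/len_a) / (counts_x/len_x); None (undefined) when the X copy
    has zero reads.  Scale-invariant in the counts.
    """
    if len_a <= 0 or len_x <= 0:
        raise ValidationError("lengths must be positive")
    if counts_a < 0 or counts_x < 0:
        raise ValidationError("counts must be non-negative")
    if counts_x == 0:
        return None
    return (counts_a / len_a) / (counts_x / len_x)


def build_profile(
    copy: GeneCopy,
    assignment: AssignmentResult,
    tissue_panel: tuple[str, ...],
    config: AnalysisConfig,
    x_copy: Optional[GeneCopy] = None,
) -> ExpressionProfile:
    """Assemble the per-tissue profile (and pattern call) for one copy."""
    counts = {t: assignment.counts.get(copy.label, {}).get(t, 0) for t in tissue_panel}
    len_kb = len(copy.cds) / 1000.0 if copy.cds else None
    if not len_kb:
        raise ValidationError(f"copy {copy.label} has no sequence")
    normalized = {t: c / len_kb for t, c in counts.items()}
    ratios: dict[str, Optional[float]] = {}
    if x_copy is not None and x_copy.cds:
        x_counts = assignment.counts.get(x_copy.label, {})
        for t in tissue_panel:
            ratios[t] = expression_ratio(
                counts[t], len(copy.cds), x_counts.get(t, 0), len(x_copy.cds)
            )
    profile = ExpressionProfile(
        copy=copy, counts=counts, normalized=normalized, ratio_vs_x=ratios
    )
    profile.pattern, profile.breadth = classify_pattern(profile, tissue_panel, config)
    return profile


def has_transcription_evidence(profile: ExpressionProfile, config: AnalysisConfig) -> bool:
    """True iff at least one tissue reaches ``min_reads_expressed`` reads."""
    return any(c >= config.min_reads_expressed for c in profile.counts.values())


def classify_pattern(
    profile: ExpressionProfile, tissue_panel: tuple[str, ...], config: AnalysisConfig
) -> tuple[str, int]:
    """(pattern, breadth) with pattern in {broad, testis_specific, silent}.

    breadth counts tissues with >= ``min_reads_expressed`` assigned reads.
    testis_specific: expressed in testis with the testis level at least
    ``testis_fold_min`` times the best non-testis level.  Expressed but
    neither silent nor testis-specific is classified broad (including the
    degenerate single-non-testis-tissue case).
    """
    if "testis" not in tissue_panel:
        raise ValidationError("tissue panel must include a 'testis' tissue")
    expressed = {
        t for t in tissue_panel
        if profile.counts.get(t, 0) >= config.min_reads_expressed
    }
    breadth = len(expressed)
    if breadth == 0:
        return "silent", 0
    testis_level = profile.normalized.get("testis", 0.0)
    other_max = max(
        (profile.normalized.get(t, 0.0) for t in tissue_panel if t != "testis"),
        default=0.0,
    )
    if "testis" in expressed and testis_level >= config.testis_fold_min * other_max:
        return "testis_specific", breadth
    return "broad", breadth
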