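"""Open-reading-frame integrity screen.

A transposed copy is only a rescue candidate if it kept an intact ORF
relative to its sex-linked counterpart.  Translation is frame 0 with the
standard genetic code; codons containing N translate as unknown and are
never counted as stops (assembly gaps must not masquerade as
pseudogenizing mutations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable

from .types import AnalysisConfig, GeneCopy, ValidationError

log = logging.getLogger("yrescue.orf")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop, 'X' for any codon containing N."""
    codon = codon.upper()
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD.forward_table[codon]


@dataclass(frozen=True)
class OrfReport:
    has_start: bool
    first_premature_stop_codon_index: Optional[int]
    orf_length_codons: int
    length_ratio_vs_reference: float
    status: str  # intact | truncated | disrupted


def scan_orf(cds: str) -> tuple[bool, Optional[int], int]:
    """Scan a CDS in frame 0.

    Returns (has_start, first_premature_stop_codon_index, orf_length_codons).
    A stop in the final complete codon is terminal, not premature; the ORF
    length counts codons before the first stop (or all complete codons).
    """
    if len(cds) < 3:
        raise ValidationError(f"cds shorter than 3 nt ({len(cds)})")
    cds = cds.upper()
    n_codons = len(cds) // 3
    has_start = cds[:3] == "ATG"
    first_stop: Optional[int] = None
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if "N" not in codon and codon in STOP_CODONS:
            first_stop = i
            break
    if first_stop is None:
        return has_start, None, n_codons
    premature = first_stop if first_stop < n_codons - 1 else None
    return has_start, premature, first_stop


def assess_integrity(
    candidate: GeneCopy, reference: GeneCopy, config: AnalysisConfig
) -> OrfReport:
    """Classify a candidate's ORF as intact/truncated/disrupted vs its
    sex-linked counterpart.

    intact: no premature stop, length divisible by 3, ORF length at least
    ``orf_length_ratio_min`` of the reference ORF.  truncated: clean frame
    but too short.  disrupted: premature stop or broken frame.
    """
    if candidate.cds is None or reference.cds is None:
        raise ValidationError("assess_integrity requires sequences on both copies")
    has_start, premature, orf_len = scan_orf(candidate.cds)
    ref_has_start, ref_premature, ref_len = scan_orf(reference.cds)
    if ref_premature is not None:
        log.warning(
            "reference %s/%s/%s is itself ORF-disrupted (stop at codon %d); "
            "comparison performed against its full-length frame",
            reference.family,
            reference.species,
            reference.locus_id,
            ref_premature,
        )
        # a broken reference says nothing about the candidate; compare
        # against the reference's full complement of codons instead
        ref_len = len(reference.cds) // 3
        if reference.cds[-3:].upper() in STOP_CODONS:
            ref_len -= 1
    if ref_len <= 0:
        raise ValidationError("reference ORF has no codons")
    ratio = orf_len / ref_len
    frame_ok = len(candidate.cds) % 3 == 0
    if premature is not None or not frame_ok:
        status = "disrupted"
    elif ratio >= config.orf_length_ratio_min:
        status = "intact"
    else:
        status = "truncated"
    return OrfReport(
        has_start=has_start,
        first_premature_stop_codon_index=premature,
        orf_length_codons=orf_len,
        length_ratio_vs_reference=ratio,
        status=status,
    )
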