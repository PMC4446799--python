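"""Protein-guided codon alignment.

Gene-family CDS are aligned at the protein level (center-star multiple
alignment: the center sequence is the one with the highest summed pairwise
alignment score; every other sequence is aligned to it by global
Needleman–Wunsch with BLOSUM62 and affine gaps, and the pairwise
alignments are merged under once-a-gap-always-a-gap).  The protein
alignment is then back-threaded onto the codons, so every gap run is a
multiple of 3 and downstream dN/dS and distance calculations stay in
frame.  Disrupted sequences are translated up to their first stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .orf import STOP_CODONS, translate_codon
from .types import GeneCopy, ValidationError

log = logging.getLogger("yrescue.align")


@dataclass
class MultipleAlignment:
    taxa: tuple[str, ...]
    rows: tuple[str, ...]          # aligned nucleotide (codon) strings
    codon_threaded: bool = True

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValidationError("alignment rows differ in length")
        if self.codon_threaded and self.rows:
            if len(self.rows[0]) % 3 != 0:
                raise ValidationError("codon-threaded alignment length not divisible by 3")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def pair(self, taxon_a: str, taxon_b: str) -> tuple[str, str]:
        return self.row(taxon_a), self.row(taxon_b)


def make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def translatable_codons(cds: str) -> list[str]:
    """Complete codons up to (excluding) the first stop; empty if the CDS
    opens with a stop codon."""
    codons = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3].upper()
        if "N" not in codon and codon in STOP_CODONS:
            break
        codons.append(codon)
    return codons


def _pairwise(aligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _merge_center_star(center: str, pairs: list[tuple[str, str]]) -> list[str]:
    """Merge pairwise (center, other) alignments into one MSA.

    Returns rows: first the center, then each other sequence, all padded to
    the union gap pattern of the center.
    """
    L = len(center)
    # per alignment: inserted-run before center residue i (and after the last)
    runs_per_aln: list[list[str]] = []
    aligned_to: list[list[str]] = []
    for c_aln, s_aln in pairs:
        runs = [""] * (L + 1)
        aligned = [""] * L
        ci = 0
        for cc, sc in zip(c_aln, s_aln):
            if cc == "-":
                runs[ci] += sc
            else:
                aligned[ci] = sc
                ci += 1
        if ci != L:
            raise ValidationError("pairwise alignment does not cover the center sequence")
        runs_per_aln.append(runs)
        aligned_to.append(aligned)
    ins = [max((len(r[i]) for r in runs_per_aln), default=0) for i in range(L + 1)]
    center_row = "".join(
        "-" * ins[i] + (center[i] if i < L else "") for i in range(L + 1)
    )
    rows = [center_row]
    for runs, aligned in zip(runs_per_aln, aligned_to):
        parts = []
        for i in range(L + 1):
            parts.append(runs[i] + "-" * (ins[i] - len(runs[i])))
            if i < L:
                parts.append(aligned[i])
        rows.append("".join(parts))
    return rows


def align_proteins(labels: list[str], proteins: list[str]) -> tuple[list[str], list[str]]:
    """Center-star protein MSA; returns (labels, aligned rows) in input order."""
    if len(proteins) < 2:
        raise ValidationError("need at least 2 sequences to align")
    if len(proteins) == 2 and proteins[0] == proteins[1]:
        return labels, list(proteins)
    if len(set(proteins)) == 1:
        return labels, list(proteins)
    aligner = make_protein_aligner()
    n = len(proteins)
    scores = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(proteins[i], proteins[j])
            scores[i] += s
            scores[j] += s
    center = max(range(n), key=lambda i: (scores[i], -i))
    others = [i for i in range(n) if i != center]
    pairs = [_pairwise(aligner, proteins[center], proteins[i]) for i in others]
    merged = _merge_center_star(proteins[center], pairs)
    rows = [""] * n
    rows[center] = merged[0]
    for k, i in enumerate(others):
        rows[i] = merged[k + 1]
    return labels, rows


def thread_codons(protein_row: str, codons: list[str]) -> str:
    out = []
    ci = 0
    for aa in protein_row:
        if aa == "-":
            out.append("---")
        else:
            out.append(codons[ci])
            ci += 1
    if ci != len(codons):
        raise ValidationError("protein row does not match codon count")
    return "".join(out)


def align_codons(copies: list[GeneCopy]) -> MultipleAlignment:
    """Codon-threaded multiple alignment of a gene family's copies.

    Each CDS is translated (terminal stop stripped; disrupted copies up to
    their first stop), proteins are center-star aligned, and the protein
    alignment is threaded back onto codons.  Untranslatable copies (first
    codon is a stop, or no sequence) are excluded with a warning.
    """
    labels: list[str] = []
    prots: list[str] = []
    codon_lists: list[list[str]] = []
    for c in copies:
        if c.cds is None:
            log.warning("copy %s has no sequence; excluded from alignment", c.label)
            continue
        codons = translatable_codons(c.cds)
        if not codons:
            log.warning("copy %s untranslatable; excluded from alignment", c.label)
            continue
        labels.append(c.label)
        prots.append("".join(translate_codon(cd) for cd in codons))
        codon_lists.append(codons)
    if len(labels) < 2:
        raise ValidationError("fewer than 2 translatable copies to align")
    labels, prot_rows = align_proteins(labels, prots)
    nt_rows = tuple(
        thread_codons(row, codons) for row, codons in zip(prot_rows, codon_lists)
    )
    return MultipleAlignment(taxa=tuple(labels), rows=nt_rows, codon_threaded=True)
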