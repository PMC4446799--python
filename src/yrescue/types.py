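"""Core domain types shared across the pipeline.

The pipeline reasons about *gene families* (e.g. EIF1A) whose members are
X-linked, Y-linked or autosomal *copies* in particular species.  A
:class:`GeneCopy` is one such homolog; a :class:`HomologTable` is the
presence/absence matrix over all copies; :class:`AnalysisConfig` carries
every tunable threshold of the analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import yaml

VALID_CHROM_CLASSES = ("X", "Y", "A")
VALID_MECHANISMS = ("retro", "dna", "ancestral", "unknown")
DNA_ALPHABET = set("ACGTN")


class ValidationError(ValueError):
    """An input object violates one of its declared invariants."""


@dataclass(frozen=True)
class GeneCopy:
    """One homolog of a gene family in one species.

    ``cds`` may be ``None`` for curated presence-only entries (sequence not
    available); when present it must be an upper-case DNA string of length
    >= 3.  ``mechanism_hint`` in {retro, dna} is only meaningful for
    autosomal copies.
    """

    family: str
    species: str
    chrom_class: str
    locus_id: str
    cds: Optional[str] = None
    has_introns: bool = True
    mechanism_hint: str = "unknown"

    def __post_init__(self) -> None:
        if self.chrom_class not in VALID_CHROM_CLASSES:
            raise ValidationError(
                f"chrom_class must be one of {VALID_CHROM_CLASSES}, got {self.chrom_class!r}"
            )
        if self.mechanism_hint not in VALID_MECHANISMS:
            raise ValidationError(
                f"mechanism_hint must be one of {VALID_MECHANISMS}, got {self.mechanism_hint!r}"
            )
        if self.mechanism_hint in ("retro", "dna") and self.chrom_class != "A":
            raise ValidationError(
                f"mechanism_hint={self.mechanism_hint!r} requires chrom_class='A' "
                f"({self.family}/{self.species}/{self.locus_id})"
            )
        if self.cds is not None:
            if len(self.cds) < 3:
                raise ValidationError(
                    f"cds length must be >= 3 ({self.family}/{self.species}/{self.locus_id})"
                )
            bad = set(self.cds) - DNA_ALPHABET
            if bad:
                raise ValidationError(
                    f"cds contains non-ACGTN characters {sorted(bad)} "
                    f"({self.family}/{self.species}/{self.locus_id})"
                )

    @property
    def label(self) -> str:
        """Stable taxon label used in alignments and trees."""
        return f"{self.species}|{self.chrom_class}|{self.locus_id}"


class HomologTable:
    """Set of :class:`GeneCopy` entries with a presence/absence view.

    Invariants: at most one Y-linked copy per (family, species) — the study
    is restricted to genes that are single-copy on the Y — and no duplicate
    (family, species, locus_id).
    """

    def __init__(self, entries: Iterable[GeneCopy]):
        self.entries: list[GeneCopy] = list(entries)
        seen_keys: set[tuple[str, str, str]] = set()
        y_seen: set[tuple[str, str]] = set()
        for c in self.entries:
            key = (c.family, c.species, c.locus_id)
            if key in seen_keys:
                raise ValidationError(f"duplicate homolog entry {key}")
            seen_keys.add(key)
            if c.chrom_class == "Y":
                yk = (c.family, c.species)
                if yk in y_seen:
                    raise ValidationError(
                        f"more than one Y-linked copy for {yk}; the analysis is "
                        "restricted to single-copy Y genes"
                    )
                y_seen.add(yk)

    def presence(self, family: str, species: str, chrom_class: str) -> bool:
        return any(
            c.family == family and c.species == species and c.chrom_class == chrom_class
            for c in self.entries
        )

    def families(self) -> list[str]:
        return sorted({c.family for c in self.entries})

    def species(self) -> list[str]:
        return sorted({c.species for c in self.entries})

    def copies(
        self,
        family: Optional[str] = None,
        species: Optional[str] = None,
        chrom_class: Optional[str] = None,
    ) -> list[GeneCopy]:
        out = []
        for c in self.entries:
            if family is not None and c.family != family:
                continue
            if species is not None and c.species != species:
                continue
            if chrom_class is not None and c.chrom_class != chrom_class:
                continue
            out.append(c)
        return out

    def family_scope(self, family: str) -> list[str]:
        """Species in which the family is represented by at least one copy.

        Presence/absence reasoning (Dollo parsimony) is restricted to this
        scope: species where a family does not exist at all (e.g. genes of
        the X/Y-added region in marsupials) carry no signal about Y loss.
        """
        return sorted({c.species for c in self.entries if c.family == family})

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AnalysisConfig:
    """Thresholds of the rescue-detection analysis.

    recency_threshold
        Autosomal copies closer than this uncorrected nucleotide distance to
        their parental copy are dismissed as too young to have faced
        selection (default 0.02, i.e. <2% divergence).
    bootstrap_replicates / bootstrap_support_min
        Number of codon-column bootstrap replicates and the minimum percent
        support for an X/Y parental-origin verdict.
    orf_length_ratio_min
        Minimum ORF length relative to the sex-linked counterpart for the
        "intact" verdict.
    min_reads_expressed
        Minimum assigned reads in a tissue to count it as expressed.
    testis_fold_min
        Fold excess of testis over the best non-testis tissue for a
        testis-specific call.
    synteny_min_shared_flanks
        Minimum shared, order-consistent flanking-gene symbols for two loci
        to be called syntenic.
    """

    recency_threshold: float = 0.02
    bootstrap_replicates: int = 100
    bootstrap_support_min: float = 70.0
    orf_length_ratio_min: float = 0.95
    min_reads_expressed: int = 10
    testis_fold_min: float = 5.0
    synteny_min_shared_flanks: int = 2
    random_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "recency_threshold",
            "bootstrap_replicates",
            "bootstrap_support_min",
            "orf_length_ratio_min",
            "min_reads_expressed",
            "testis_fold_min",
            "synteny_min_shared_flanks",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.recency_threshold >= 1:
            raise ValidationError("recency_threshold must be < 1")
        if self.bootstrap_support_min > 100:
            raise ValidationError("bootstrap_support_min must be <= 100")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Load from a YAML or JSON mapping (keys mirror the field names)."""
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class EvidenceRecord:
    """Functionality evidence for one autosomal candidate copy.

    ``orf_status`` in {intact, truncated, disrupted}; ``recency`` in
    {keep, dismiss} (dismiss = <2% diverged from the parental copy, too
    young to have faced selection); ``omega`` is the pairwise dN/dS against
    the closest carrier of the same locus group, when computable.
    """

    family: str
    species: str
    locus_id: str
    orf_status: str
    transcribed: bool
    recency: str
    omega: Optional[float] = None
    expression_pattern: Optional[str] = None

    def __post_init__(self) -> None:
        if self.orf_status not in ("intact", "truncated", "disrupted"):
            raise ValidationError(f"bad orf_status {self.orf_status!r}")
        if self.recency not in ("keep", "dismiss"):
            raise ValidationError(f"bad recency {self.recency!r}")

    @property
    def passes(self) -> bool:
        """True iff the copy meets all three functionality criteria."""
        return self.orf_status == "intact" and self.transcribed and self.recency == "keep"


@dataclass(frozen=True)
class Read:
    identifier: str
    sequence: str
    tissue: str
    species: str


@dataclass
class ReadSet:
    """Reads from one species, tissue-stratified."""

    reads: list[Read]
    read_length: int
    tissue_panel: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        species = {r.species for r in self.reads}
        if len(species) > 1:
            raise ValidationError(f"ReadSet mixes species: {sorted(species)}")
        if self.tissue_panel:
            bad = {r.tissue for r in self.reads} - set(self.tissue_panel)
            if bad:
                raise ValidationError(f"reads carry undeclared tissue labels: {sorted(bad)}")

    @property
    def species(self) -> Optional[str]:
        return self.reads[0].species if self.reads else None

    def by_tissue(self) -> dict[str, list[Read]]:
        out: dict[str, list[Read]] = {}
        for r in self.reads:
            out.setdefault(r.tissue, []).append(r)
        return out
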