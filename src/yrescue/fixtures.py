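"""Packaged curated fixture: the study's presence/absence matrix, synteny
groupings and evidence verdicts over 13 mammals.

Only the two divergence dates the analysis actually leans on (mouse–rat at
25 my, opossum–wallaby at 88 my) are treated as authoritative; the other
node ages are standard TimeTree-style values and serve only to shape the
tree.  Evidence rows are curated functionality verdicts per autosomal
locus (the OWM EIF2S3 copies are curated intact: their reading frames
could not be checked against fragmentary assemblies but the loci behave
as functional genes)."""

from __future__ import annotations

from importlib import resources

from . import io as yio
from .tree import SpeciesTree, read_species_tree
from .types import EvidenceRecord, HomologTable


def _data_path(name: str):
    return resources.files("yrescue").joinpath("data", name)


def curated_tree() -> SpeciesTree:
    with resources.as_file(_data_path("species_tree.nwk")) as p:
        return read_species_tree(p)


def curated_homologs() -> HomologTable:
    with resources.as_file(_data_path("homologs.tsv")) as p:
        return yio.read_homolog_table(p)


def curated_synteny():
    with resources.as_file(_data_path("synteny.tsv")) as p:
        return yio.read_synteny_table(p)


def curated_evidence() -> list[EvidenceRecord]:
    with resources.as_file(_data_path("evidence.tsv")) as p:
        return yio.read_evidence_table(p)


def load_curated_fixture():
    """(HomologTable, SpeciesTree, synteny records, evidence records)."""
    return curated_homologs(), curated_tree(), curated_synteny(), curated_evidence()
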