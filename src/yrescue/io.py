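"""Readers and writers for the pipeline's plain-text formats.

FASTA identifiers are preserved verbatim (the full header line after '>'),
sequences are upper-cased and RNA 'U' is normalized to 'T'.  FASTQ goes
through Biopython; read metadata (species, tissue) is encoded in the read
identifier as ``name|species|tissue``.  Tables are TSV via pandas.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .types import (
    EvidenceRecord,
    GeneCopy,
    HomologTable,
    Read,
    ReadSet,
    ValidationError,
)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (identifier, sequence) pairs.

    The identifier is the full header line after '>', verbatim.  A sequence
    line appearing before any header is a parse error naming the line.
    """
    records: list[tuple[str, str]] = []
    header: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}: line {lineno}: sequence data before first FASTA header"
                    )
                chunks.append(line.strip().upper().replace("U", "T"))
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ read sets

def write_readset(readset: ReadSet, path) -> None:
    """Write reads as Phred+33 FASTQ ('I' qualities; the assigner ignores them)."""
    with open(path, "w") as fh:
        for r in readset.reads:
            fh.write(f"@{r.identifier}|{r.species}|{r.tissue}\n{r.sequence}\n+\n")
            fh.write("I" * len(r.sequence) + "\n")


def read_readset(path, tissue_panel: tuple[str, ...] = ()) -> ReadSet:
    reads = []
    length = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise ParseError(
                f"{path}: read id {rec.id!r} lacks the name|species|tissue encoding"
            )
        tissue = parts[-1]
        species = parts[-2]
        name = "|".join(parts[:-2])
        seq = str(rec.seq).upper().replace("U", "T")
        reads.append(Read(identifier=name, sequence=seq, tissue=tissue, species=species))
        length = max(length, len(seq))
    return ReadSet(reads=reads, read_length=length, tissue_panel=tissue_panel)


# ---------------------------------------------------------------------------
# Homolog table (presence/absence matrix rows)

HOMOLOG_COLUMNS = [
    "family",
    "species",
    "chrom_class",
    "locus_id",
    "has_introns",
    "mechanism_hint",
]


def write_homolog_table(table: HomologTable, path) -> None:
    rows = [
        {
            "family": c.family,
            "species": c.species,
            "chrom_class": c.chrom_class,
            "locus_id": c.locus_id,
            "has_introns": c.has_introns,
            "mechanism_hint": c.mechanism_hint,
        }
        for c in table.entries
    ]
    pd.DataFrame(rows, columns=HOMOLOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_homolog_table(path, cds_by_label: Optional[dict[str, str]] = None) -> HomologTable:
    """Read a homolog TSV; optionally attach CDS keyed by GeneCopy.label."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(HOMOLOG_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: homolog table missing columns {sorted(missing)}")
    copies = []
    for _, row in df.iterrows():
        label = f"{row['species']}|{row['chrom_class']}|{row['locus_id']}"
        copies.append(
            GeneCopy(
                family=row["family"],
                species=row["species"],
                chrom_class=row["chrom_class"],
                locus_id=row["locus_id"],
                cds=(cds_by_label or {}).get(label),
                has_introns=str(row["has_introns"]).strip().lower() in ("true", "1", "yes"),
                mechanism_hint=row.get("mechanism_hint", "unknown") or "unknown",
            )
        )
    return HomologTable(copies)


# ---------------------------------------------------------------------------
# Synteny table

def write_synteny_table(records, path) -> None:
    rows = [
        {
            "family": r.family,
            "species": r.species,
            "locus_id": r.locus_id,
            "upstream_flanks": ",".join(r.upstream),
            "downstream_flanks": ",".join(r.downstream),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["family", "species", "locus_id", "upstream_flanks", "downstream_flanks"],
    ).to_csv(path, sep="\t", index=False)


def read_synteny_table(path):
    from .synteny import SyntenyRecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            SyntenyRecord(
                family=row["family"],
                species=row["species"],
                locus_id=row["locus_id"],
                upstream=tuple(s for s in row["upstream_flanks"].split(",") if s),
                downstream=tuple(s for s in row["downstream_flanks"].split(",") if s),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Evidence table (curated or computed per-candidate verdicts)

EVIDENCE_COLUMNS = [
    "family",
    "species",
    "locus_id",
    "orf_status",
    "transcribed",
    "recency",
    "omega",
    "expression_pattern",
]


def write_evidence_table(records: Iterable[EvidenceRecord], path) -> None:
    rows = [
        {
            "family": r.family,
            "species": r.species,
            "locus_id": r.locus_id,
            "orf_status": r.orf_status,
            "transcribed": r.transcribed,
            "recency": r.recency,
            "omega": "" if r.omega is None else f"{r.omega:.6g}",
            "expression_pattern": r.expression_pattern or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_evidence_table(path) -> list[EvidenceRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EVIDENCE_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: evidence table missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        omega = row.get("omega", "")
        out.append(
            EvidenceRecord(
                family=row["family"],
                species=row["species"],
                locus_id=row["locus_id"],
                orf_status=row["orf_status"],
                transcribed=str(row["transcribed"]).strip().lower() in ("true", "1", "yes"),
                recency=row["recency"],
                omega=float(omega) if omega not in ("", None) else None,
                expression_pattern=row.get("expression_pattern") or None,
            )
        )
    return out
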