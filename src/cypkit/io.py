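"""Readers and writers for the external formats the pipeline touches.

Internal convention: every interval computation elsewhere in the package uses
0-based half-open coordinates; this module stores and emits the native
convention of each format (FASTA as-is, GFF3 1-based inclusive) and converts
at the boundary.  FASTA is written wrapped at 60 columns.  All tabular
pipeline outputs are TSV with one header row and ``#``-prefixed metadata
lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGT")


@dataclass
class SequenceRecord:
    """A protein or CDS sequence with its identifier."""

    id: str
    sequence: str
    kind: str = "protein"  # {"protein", "cds"}
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.kind not in ("protein", "cds"):
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        self.sequence = self.sequence.upper()
        if self.kind == "protein":
            bad = set(self.sequence) - PROTEIN_ALPHABET
            if bad:
                raise ValueError(
                    f"record {self.id!r}: ambiguous residues {sorted(bad)} not "
                    "allowed (only the 20 standard amino acids plus X)"
                )
        else:
            if len(self.sequence) == 0:
                raise ValueError(f"record {self.id!r}: empty CDS")
            bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
            if bad:
                raise ValueError(f"record {self.id!r}: non-ACGT bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A gene with genomic location and exon/CDS structure.

    Coordinates are stored 1-based inclusive (the GFF3 convention); exons and
    CDS segments are kept in transcription order, i.e. reversed relative to
    genomic order on the minus strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def cds_complete(self) -> bool:
        """Whether the total CDS length is divisible by three (a flag, not an error)."""
        return self.cds_length % 3 == 0


@dataclass
class EvidenceRow:
    """One row of externally supplied evidence (hmmsearch or BLAST/DIAMOND)."""

    query_id: str
    source: str  # {"domain_scan", "similarity"}
    score: float
    evalue: float
    region: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"evidence for {self.query_id}: negative E-value")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, order preserved.

    Duplicate ids raise; an empty file yields an empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id) :].strip() if rec.description else ""
            records.append(
                SequenceRecord(rec.id, str(rec.seq), kind=kind, description=desc)
            )
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, sequences wrapped at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def _transcription_sorted(
    segments: list[tuple[int, int]], strand: str, label: str
) -> list[tuple[int, int]]:
    genomic = sorted(segments)
    for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
        if s2 <= e1:
            raise ValueError(f"{label}: overlapping segments {s1}-{e1} and {s2}-{e2}")
    # files carry genomic order; transcription order is derived from strand
    if segments and genomic != segments:
        warnings.warn(f"{label}: segments out of genomic order; reordered", stacklevel=3)
    return genomic if strand == "+" else genomic[::-1]


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    The one accepted dialect links gene -> mRNA -> exon/CDS by ID/Parent
    attributes; when a gene has several mRNAs the one with the longest total
    CDS is kept (logged via a warning).  A CDS feature whose parent chain does
    not reach a gene is an error.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for cds in db.features_of_type("CDS"):
        if not list(db.parents(cds.id, featuretype="gene")):
            raise ValueError(f"CDS feature {cds.id!r} has no parent gene")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene.id, featuretype="mRNA"))
        containers = mrnas if mrnas else [gene]
        best, best_len = None, -1
        for t in containers:
            clen = sum(c.end - c.start + 1 for c in db.children(t.id, featuretype="CDS", order_by="start"))
            if clen > best_len:
                best, best_len = t, clen
        if len(containers) > 1:
            warnings.warn(
                f"gene {gene.id}: {len(containers)} isoforms; kept longest CDS ({best.id})",
                stacklevel=2,
            )
        exons = [
            (f.start, f.end)
            for f in db.children(best.id, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start, f.end)
            for f in db.children(best.id, featuretype="CDS", order_by="start")
        ]
        strand = gene.strand if gene.strand in ("+", "-") else "+"
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=strand,
                start=gene.start,
                end=gene.end,
                exons=_transcription_sorted(exons, strand, f"gene {gene.id} exons"),
                cds_segments=_transcription_sorted(cds, strand, f"gene {gene.id} CDS"),
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id};Name={m.gene_id}"
            fh.write(
                f"{m.chromosome}\tcypkit\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.chromosome}\tcypkit\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            # emit in genomic order (the native convention); the reader restores
            # transcription order from the strand
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chromosome}\tcypkit\texon\t{s}\t{e}\t.\t{m.strand}\t.\tParent={mrna_id}\n"
                )
            for s, e in sorted(m.cds_segments):
                fh.write(
                    f"{m.chromosome}\tcypkit\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\tParent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# External evidence tables


def read_evidence_table(path: str | Path, dialect: str) -> list[EvidenceRow]:
    """Parse an external-evidence table.

    ``dialect`` is ``"blast_outfmt6"`` (tab-separated 12-column BLAST/DIAMOND
    output; mapped to source="similarity") or ``"hmmsearch_domtblout"``
    (whitespace-separated HMMER3 per-domain table; source="domain_scan").
    Comment lines (``#``) are skipped; malformed rows are skipped with a
    warning naming the line number.
    """
    if dialect not in ("blast_outfmt6", "hmmsearch_domtblout"):
        raise ValueError(f"unknown evidence dialect {dialect!r}")
    rows: list[EvidenceRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if dialect == "blast_outfmt6" else line.split()
            try:
                if dialect == "blast_outfmt6":
                    rows.append(
                        EvidenceRow(
                            query_id=fields[0],
                            source="similarity",
                            score=float(fields[11]),
                            evalue=float(fields[10]),
                            region=(int(fields[6]), int(fields[7])),
                        )
                    )
                else:  # hmmsearch --domtblout: target name first, i-Evalue col 13
                    rows.append(
                        EvidenceRow(
                            query_id=fields[0],
                            source="domain_scan",
                            score=float(fields[13]),
                            evalue=float(fields[12]),
                            region=(int(fields[17]), int(fields[18])),
                        )
                    )
            except (IndexError, ValueError):
                warnings.warn(f"{path}:{lineno}: malformed row skipped", stacklevel=2)
    return rows


# ---------------------------------------------------------------------------
# TSV output with metadata header


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: Optional[dict] = None) -> None:
    """Write a DataFrame as TSV with '#key=value' metadata lines above the header."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
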