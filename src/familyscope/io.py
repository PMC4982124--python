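"""File formats and in-memory records shared by every pipeline stage.

The pipeline consumes four plain-text inputs per species: a proteome FASTA,
a genome FASTA, gene models in GFF3 (gene/mRNA/CDS, with a
``primary=true|false`` attribute on mRNA lines) and a tab-separated domain
table in an InterProScan-like dialect (protein_id, accession, start, end;
1-based inclusive protein coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

GFF_COLUMNS = ("seqid", "source", "type", "start", "end",
               "score", "strand", "phase", "attributes")


class InputError(ValueError):
    """A malformed or inconsistent input file."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence tied to its gene model."""
    protein_id: str
    species: str
    sequence: str
    gene_id: str
    is_primary_transcript: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain hit on a protein (1-based inclusive coordinates)."""
    protein_id: str
    accession: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneLocus:
    """Genomic location of one gene (1-based inclusive, stranded)."""
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str],
                width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3

def parse_gff_attributes(attributes: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for field in attributes.strip().split(";"):
        if field and "=" in field:
            key, value = field.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a DataFrame with an extra parsed ``attr`` dict column."""
    df = pd.read_csv(path, sep="\t", comment="#", names=GFF_COLUMNS,
                     dtype={"seqid": str, "start": int, "end": int},
                     na_filter=False)
    df["attr"] = df["attributes"].map(parse_gff_attributes)
    return df


def write_gff3(path: str | Path, rows: Iterable[Mapping]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in GFF_COLUMNS) + "\n")


def gene_loci_from_gff(gff: pd.DataFrame) -> list[GeneLocus]:
    genes = gff[gff["type"] == "gene"]
    return [GeneLocus(gene_id=row.attr["ID"], chromosome=row.seqid,
                      start=int(row.start), end=int(row.end),
                      strand=row.strand)
            for row in genes.itertuples()]


def _primary_flags(gff: pd.DataFrame) -> dict[str, tuple[str, bool]]:
    """Map protein/mRNA id -> (gene id, primary flag)."""
    out = {}
    for row in gff[gff["type"] == "mRNA"].itertuples():
        attr = row.attr
        out[attr["ID"]] = (attr.get("Parent", attr["ID"]),
                           attr.get("primary", "true").lower() == "true")
    return out


# ---------------------------------------------------------------------------
# Domain table

DOMAIN_COLUMNS = ("protein_id", "accession", "start", "end")


def write_domain_table(path: str | Path,
                       annotations: Iterable[DomainAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DOMAIN_COLUMNS) + "\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.accession}\t{a.start}\t{a.end}\n")


def read_domain_table(path: str | Path,
                      protein_lengths: Mapping[str, int] | None = None,
                      ) -> list[DomainAnnotation]:
    """Read the domain TSV, validating coordinates against protein lengths.

    Raises :class:`InputError` naming the offending row (1-based, counting
    the header) on any malformed or out-of-range row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str,
                                            "accession": str})
    missing = [c for c in DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"domain table {path}: missing columns {missing}")
    out: list[DomainAnnotation] = []
    for i, row in enumerate(df.itertuples(), start=2):
        start, end = int(row.start), int(row.end)
        if not (1 <= start <= end):
            raise InputError(
                f"domain table {path}, row {i}: bad interval {start}..{end}")
        if protein_lengths is not None:
            if row.protein_id not in protein_lengths:
                raise InputError(
                    f"domain table {path}, row {i}: unknown protein "
                    f"{row.protein_id!r}")
            if end > protein_lengths[row.protein_id]:
                raise InputError(
                    f"domain table {path}, row {i}: end {end} exceeds "
                    f"length of {row.protein_id} "
                    f"({protein_lengths[row.protein_id]})")
        out.append(DomainAnnotation(row.protein_id, row.accession, start, end))
    return out


# ---------------------------------------------------------------------------
# Bundle loading

def load_inputs(proteome_path: str | Path, gff_path: str | Path,
                domains_path: str | Path, species: str = "species",
                ) -> tuple[list[ProteinRecord], list[DomainAnnotation]]:
    """Load one species bundle into linked records and annotations."""
    proteome = read_fasta(proteome_path)
    gff = read_gff3(gff_path)
    flags = _primary_flags(gff)
    records = []
    for pid, seq in proteome.items():
        gene_id, primary = flags.get(pid, (pid, True))
        if pid not in flags:
            log.warning("protein %s has no mRNA entry in %s; assuming "
                        "primary, gene id = protein id", pid, gff_path)
        records.append(ProteinRecord(pid, species, seq, gene_id, primary))
    lengths = {pid: len(seq) for pid, seq in proteome.items()}
    annotations = read_domain_table(domains_path, lengths)
    return records, annotations
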