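"""Sequence I/O and six-frame translation with genomic coordinate mapping.

Readers and writers wrap Biopython for the standard formats; the domain
records used throughout the package carry the small amount of validation the
pipeline relies on (uppercase alphabets, 1-based inclusive coordinates in
everything serialized, 0-based half-open coordinates internally).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (AlphabetError, CoordinateError, DegenerateInputError,
                     FastaFormatError)

NUCLEOTIDE_ALPHABET = set("ACGTN")
# 20 standard residues plus X (unknown) and * (stop)
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_CODON_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
_FORWARD = dict(_CODON_TABLE.forward_table)
_FORWARD.update({codon: "*" for codon in _CODON_TABLE.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Standard-code translation; any codon containing N yields X.

    The conservative N rule matters downstream: an X never matches a
    cysteine in motif scans, so assembly gaps cannot fabricate motifs.
    """
    if "N" in codon:
        return "X"
    return _FORWARD[codon]


@dataclass(frozen=True)
class ScaffoldRecord:
    """A named nucleotide sequence (an assembly scaffold or contig)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise FastaFormatError("scaffold with empty id")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise AlphabetError(
                f"scaffold {self.id!r}: disallowed nucleotide characters "
                f"{sorted(bad)} (only A,C,G,T,N accepted)")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A named peptide sequence over the 20 standard letters plus X and *."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise FastaFormatError("protein record with empty id")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise AlphabetError(
                f"protein {self.id!r}: disallowed residue characters "
                f"{sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """One genomic feature: 1-based inclusive coordinates, as in GFF3."""

    scaffold_id: str
    start: int
    end: int
    strand: str = "."
    feature_type: str = "region"
    name: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise CoordinateError(
                f"{self.scaffold_id}:{self.start}-{self.end}: "
                "require 1 <= start <= end")
        if self.strand not in {"+", "-", "."}:
            raise CoordinateError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class TranslatedFrame:
    """One of the six reading frames of a scaffold.

    ``peptide[i]`` is encoded by the genomic interval ``codon_interval(i)``
    (1-based inclusive, on ``strand``).  Reverse-strand frames translate the
    reverse complement, so frame offsets count from the 3' end of the
    forward sequence.
    """

    scaffold_id: str
    strand: Literal["+", "-"]
    frame_offset: int
    peptide: str
    scaffold_length: int

    def codon_interval(self, index: int) -> tuple[int, int]:
        if not 0 <= index < len(self.peptide):
            raise IndexError(index)
        if self.strand == "+":
            start0 = self.frame_offset + 3 * index
            return (start0 + 1, start0 + 3)
        # index counts along the reverse complement
        end0 = self.scaffold_length - self.frame_offset - 3 * index
        return (end0 - 2, end0)

    def residue_span(self, start_index: int, end_index: int) -> tuple[int, int]:
        """Genomic interval (1-based inclusive) covering peptide
        ``[start_index, end_index]`` inclusive."""
        a = self.codon_interval(start_index)
        b = self.codon_interval(end_index)
        lo = min(a[0], b[0])
        hi = max(a[1], b[1])
        return (lo, hi)


def six_frame_translate(scaffold: ScaffoldRecord) -> list[TranslatedFrame]:
    """Translate a scaffold in all six reading frames (standard code)."""
    if scaffold.length < 3:
        raise DegenerateInputError(
            f"scaffold {scaffold.id!r} shorter than one codon")
    frames: list[TranslatedFrame] = []
    for strand, seq in (("+", scaffold.sequence),
                        ("-", reverse_complement(scaffold.sequence))):
        for offset in range(3):
            n_codons = (len(seq) - offset) // 3
            peptide = "".join(
                translate_codon(seq[offset + 3 * k: offset + 3 * k + 3])
                for k in range(n_codons))
            frames.append(TranslatedFrame(
                scaffold_id=scaffold.id, strand=strand, frame_offset=offset,
                peptide=peptide, scaffold_length=scaffold.length))
    return frames


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def _prevalidate_fasta(path: Path) -> None:
    """Cheap line-level scan so format errors can name the offending line."""
    seen_any = False
    header_line = None
    body = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if not line[1:].strip():
                    raise FastaFormatError(f"line {lineno}: empty header")
                if header_line is not None and body == 0:
                    raise FastaFormatError(
                        f"line {header_line}: record has no sequence")
                header_line, body, seen_any = lineno, 0, True
            else:
                if header_line is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence before first '>' header")
                body += len(line.strip())
    if not seen_any:
        raise FastaFormatError("no FASTA records found")
    if header_line is not None and body == 0:
        raise FastaFormatError(f"line {header_line}: record has no sequence")


def read_fasta(path, alphabet: Literal["nucleotide", "protein"]):
    """Read a FASTA file into Scaffold- or ProteinRecords.

    Sequences are uppercased on ingest; record order is preserved.  Protein
    ids must be unique within the file.
    """
    path = Path(path)
    _prevalidate_fasta(path)
    cls = ScaffoldRecord if alphabet == "nucleotide" else ProteinRecord
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if alphabet == "protein" and rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(cls(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Sequence, path) -> None:
    """Write records as 60-column wrapped FASTA (inverse of read_fasta)."""
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="")
            for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

_GFF3_ESCAPE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "%": "%25"}


def _escape_attr(value: str) -> str:
    value = value.replace("%", "%25")
    for char, code in _GFF3_ESCAPE.items():
        if char != "%":
            value = value.replace(char, code)
    return value


def _unescape_attr(value: str) -> str:
    for char, code in _GFF3_ESCAPE.items():
        value = value.replace(code, char)
    return value


def write_gff3(records: Iterable[AnnotationRecord], path,
               source: str = "ampminer") -> None:
    """Serialize annotation records as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = dict(rec.attributes)
            if rec.name and "Name" not in attrs:
                attrs["Name"] = rec.name
            if "ID" not in attrs:
                attrs["ID"] = rec.name or f"{rec.scaffold_id}:{rec.start}-{rec.end}"
            attr_text = ";".join(
                f"{k}={_escape_attr(str(v))}" for k, v in attrs.items())
            fh.write("\t".join([
                rec.scaffold_id, source, rec.feature_type,
                str(rec.start), str(rec.end), ".", rec.strand, ".",
                attr_text]) + "\n")


def read_gff3(path) -> list[AnnotationRecord]:
    """Parse a GFF3 file back into AnnotationRecords."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    records = []
    for feat in db.all_features(order_by=("seqid", "start")):
        attributes = {k: _unescape_attr(",".join(v))
                      for k, v in feat.attributes.items()}
        name = attributes.get("Name", attributes.get("ID", ""))
        records.append(AnnotationRecord(
            scaffold_id=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand or ".", feature_type=feat.featuretype,
            name=name, attributes=attributes))
    return records


def read_marker_table(path) -> list[AnnotationRecord]:
    """Read flanking-marker annotations from TSV or GFF3.

    TSV columns: scaffold_id, start, end, strand, name.
    """
    path = Path(path)
    head = path.read_text().lstrip()
    if head.startswith("##gff-version"):
        return read_gff3(path)
    records = []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        row = dict(zip(header, ln.split("\t")))
        records.append(AnnotationRecord(
            scaffold_id=row["scaffold_id"], start=int(row["start"]),
            end=int(row["end"]), strand=row.get("strand", "."),
            feature_type=row.get("feature_type", "gene"),
            name=row["name"]))
    return records
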