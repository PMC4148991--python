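"""Reading, writing and validation of the pipeline's file formats.

FASTA ingest is backed by Biopython's parser with a validation layer
enforcing unique ids and a declared alphabet; the 12-column tabular
similarity-hit format ("outfmt 6" layout) and the 2-column COG
assignment table are parsed line-by-line so that malformed rows fail
hard with a line number.

Coordinates are 0-based half-open everywhere inside the package.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

# IUPAC nucleotide codes: the four bases, N, and the ambiguity letters.
NUCLEOTIDE_ALPHABET = frozenset("ACGTNRYSWKMBDHV")
# 20 amino acids plus X (unknown) and * (stop).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "protein": PROTEIN_ALPHABET}

#: COG single-letter functional categories (J = Translation, ... S = Function unknown).
COG_CATEGORIES = tuple("JAKLBDYVTMNZWUOCGEFHIPQRS")


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


class HitTableError(ValueError):
    """Malformed similarity-hit table input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry with residues validated against a declared alphabet."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self):
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.id:
            raise ValueError("record id must be nonempty")
        residues = self.residues.upper()
        if not residues:
            raise ValueError(f"record {self.id!r}: residues must be nonempty")
        bad = set(residues) - _ALPHABETS[self.alphabet]
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} character(s) "
                f"{''.join(sorted(bad))!r}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HitRecord:
    """One similarity-search hit (query vs subject) from a 12-column table."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError(f"aln_length {self.aln_length} must be >= 1")
        if self.e_value < 0:
            raise ValueError(f"e_value {self.e_value} must be non-negative")


@dataclass
class CogAssignment:
    """COG category letters assigned to one gene."""

    gene_id: str
    categories: frozenset

    def __post_init__(self):
        cats = frozenset(self.categories)
        if not cats:
            raise ValueError(f"gene {self.gene_id!r}: assigned gene needs >= 1 category")
        bad = cats - set(COG_CATEGORIES)
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: unknown COG category {''.join(sorted(bad))!r}"
            )
        self.categories = cats


@dataclass
class GeneSet:
    """A genome's protein-coding genes: nucleotide CDS plus optional proteins.

    When ``proteins`` is absent it is filled by translating each CDS with
    the bacterial genetic code; genes whose CDS does not translate
    cleanly (length not a multiple of three, internal stop) are skipped
    for protein-level work but still counted in ``gene_count``.
    """

    genome_label: str
    genes: list = field(default_factory=list)
    proteins: list | None = None

    def __post_init__(self):
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"gene set {self.genome_label!r}: duplicate gene id {dup!r}")
        if self.proteins is not None:
            if {p.id for p in self.proteins} != set(ids):
                raise ValueError(
                    f"gene set {self.genome_label!r}: protein ids do not match gene ids"
                )

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    def translated(self) -> dict:
        """Map gene id -> protein SequenceRecord, translating CDS on demand.

        Untranslatable genes are omitted from the map (but remain in
        ``genes`` and in ``gene_count``).
        """
        if self.proteins is not None:
            return {p.id: p for p in self.proteins}
        out = {}
        for g in self.genes:
            try:
                out[g.id] = translate_cds(g)
            except ValueError:
                continue
        return out


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, alphabet: str = "nucleotide") -> list:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Ids are the first whitespace-delimited token of each header; the
    remainder is the description. Residues are uppercased and checked
    against the declared alphabet; an illegal character is reported with
    its line number, a duplicate id with the offending id. An empty file
    yields an empty list.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            try:
                records.append(
                    SequenceRecord(rec.id, str(rec.seq), desc, alphabet=alphabet)
                )
            except ValueError as exc:
                raise FastaError(
                    f"{path}:{_find_bad_line(path, rec.id, alphabet)}: {exc}"
                ) from exc
    return records


def _find_bad_line(path, rec_id: str, alphabet: str) -> int:
    """Locate the first line of record ``rec_id`` with an illegal character."""
    allowed = _ALPHABETS[alphabet]
    in_record = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == rec_id if line[1:].split() else False
                continue
            if in_record:
                if not line.strip():
                    return lineno  # blank body line: empty-record complaint
                if set(line.strip().upper()) - allowed:
                    return lineno
    return 0


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as FASTA, wrapping sequence lines at 70 columns."""
    with open(path, "wt") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for start in range(0, len(rec.residues), 70):
                handle.write(rec.residues[start:start + 70] + "\n")


def read_hit_table(path) -> list:
    """Parse a 12-column tab-separated similarity-hit table.

    Column layout: qseqid, sseqid, pident, length, mismatch, gapopen,
    qstart, qend, sstart, send, evalue, bitscore. Columns 5-10 are
    validated as numeric but ignored downstream. Malformed rows raise
    :class:`HitTableError` with the line number.
    """
    hits: list[HitRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise HitTableError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
                # middle columns must at least be numeric
                for f in fields[4:10]:
                    float(f)
            except ValueError as exc:
                raise HitTableError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_cog_table(path) -> list:
    """Parse a 2-column tab-separated COG table: gene_id, comma-joined letters."""
    out: list[CogAssignment] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            cats = frozenset(c.strip() for c in fields[1].split(",") if c.strip())
            try:
                out.append(CogAssignment(fields[0], cats))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def translate_cds(record: SequenceRecord, table: int = 11) -> SequenceRecord:
    """Translate a nucleotide CDS with the bacterial genetic code.

    A single trailing stop codon is trimmed; an internal stop codon or a
    length not divisible by three is a hard error.
    """
    if record.alphabet != "nucleotide":
        raise ValueError(f"record {record.id!r}: expected a nucleotide CDS")
    if len(record.residues) % 3 != 0:
        raise ValueError(
            f"record {record.id!r}: CDS length {len(record.residues)} not a multiple of 3"
        )
    aa = str(Seq(record.residues).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"record {record.id!r}: internal stop codon in CDS")
    if not aa:
        raise ValueError(f"record {record.id!r}: CDS translates to an empty protein")
    return SequenceRecord(record.id, aa, record.description, alphabet="protein")
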