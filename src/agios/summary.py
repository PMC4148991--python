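"""Genome composition statistics, COG category tables, and the 16S
species-delineation check.

Conventions: G+C counting is case-insensitive; among IUPAC ambiguity
codes only S (G or C) counts toward G+C, every other code — including
N — counts in the genome length but not in G+C. Coding density merges
overlapping gene intervals (0-based half-open) before counting covered
bases. COG percentages use the protein-coding gene total as the
denominator, and a gene carrying k category letters increments k
categories, so the column sum may exceed the gene total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from agios.seqio import COG_CATEGORIES, CogAssignment, SequenceRecord

#: Human-readable names of the 25 general COG functional categories.
COG_NAMES = {
    "J": "Translation",
    "A": "RNA processing and modification",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "B": "Chromatin structure and dynamics",
    "D": "Cell cycle control, mitosis and meiosis",
    "Y": "Nuclear structure",
    "V": "Defense mechanisms",
    "T": "Signal transduction mechanisms",
    "M": "Cell wall/membrane biogenesis",
    "N": "Cell motility",
    "Z": "Cytoskeleton",
    "W": "Extracellular structures",
    "U": "Intracellular trafficking and secretion",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "C": "Energy production and conversion",
    "G": "Carbohydrate transport and metabolism",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
}


def percentage(part: float, whole: float) -> float:
    """100 * part / whole. The single percentage convention used package-wide."""
    if whole <= 0:
        raise ValueError("percentage denominator must be positive")
    return 100.0 * part / whole


@dataclass
class GenomeSummary:
    """Composition and gene-count statistics of one genome."""

    genome_size_bp: int
    gc_bp: int
    coding_bp: int
    total_genes: int
    rna_genes: int
    protein_genes: int
    genes_in_cogs: int
    cog_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.protein_genes + self.rna_genes != self.total_genes:
            raise ValueError("protein_genes + rna_genes must equal total_genes")
        if self.genes_in_cogs > self.protein_genes:
            raise ValueError("genes_in_cogs cannot exceed protein_genes")

    @property
    def gc_pct(self) -> float:
        return percentage(self.gc_bp, self.genome_size_bp)

    @property
    def coding_pct(self) -> float:
        return percentage(self.coding_bp, self.genome_size_bp)

    @property
    def not_in_cogs(self) -> int:
        return self.protein_genes - self.genes_in_cogs

    def to_dict(self) -> dict:
        return {
            "genome_size_bp": self.genome_size_bp,
            "gc_bp": self.gc_bp,
            "gc_pct": round(self.gc_pct, 2),
            "coding_bp": self.coding_bp,
            "coding_pct": round(self.coding_pct, 2),
            "total_genes": self.total_genes,
            "rna_genes": self.rna_genes,
            "protein_genes": self.protein_genes,
            "genes_in_cogs": self.genes_in_cogs,
            "genes_in_cogs_pct": round(percentage(self.genes_in_cogs, self.protein_genes), 2),
            "not_in_cogs": self.not_in_cogs,
        }


@dataclass(frozen=True)
class DelineationPolicy:
    """16S rRNA identity threshold below which an isolate is a candidate
    new species (98.7% by the Stackebrandt-Ebers recommendation)."""

    threshold_pct: float = 98.7

    def __post_init__(self):
        if not 0 < self.threshold_pct <= 100:
            raise ValueError("threshold_pct outside (0, 100]")


def gc_content(contigs) -> tuple:
    """(gc_bp, genome_size_bp, gc_pct) over a collection of contigs.

    G, C and the ambiguity code S count toward gc_bp; every residue,
    N included, counts toward genome_size_bp.
    """
    contigs = list(contigs)
    if not contigs:
        raise ValueError("gc_content needs at least one contig")
    gc = size = 0
    for rec in contigs:
        s = rec.residues if isinstance(rec, SequenceRecord) else rec.upper()
        gc += s.count("G") + s.count("C") + s.count("S")
        size += len(s)
    return gc, size, percentage(gc, size)


def merge_intervals(intervals) -> list:
    """Union of 0-based half-open intervals, sorted and merged."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coding_fraction(contigs, gene_intervals: dict, merge_overlaps: bool = True) -> tuple:
    """(coding_bp, coding_pct) from per-contig gene intervals.

    ``gene_intervals`` maps contig id -> iterable of (start, end)
    0-based half-open intervals. Overlapping intervals are merged before
    counting unless ``merge_overlaps`` is False (then bases covered
    twice count twice).
    """
    contigs = list(contigs)
    lengths = {c.id: len(c) for c in contigs}
    _, size, _ = gc_content(contigs)
    coding = 0
    for contig_id, ivs in gene_intervals.items():
        if contig_id not in lengths:
            raise ValueError(f"unknown contig {contig_id!r} in gene intervals")
        L = lengths[contig_id]
        ivs = [(int(s), int(e)) for s, e in ivs]
        for s, e in ivs:
            if not (0 <= s < e <= L):
                raise ValueError(
                    f"interval [{s}, {e}) out of bounds on contig {contig_id!r} (length {L})"
                )
        if merge_overlaps:
            ivs = merge_intervals(ivs)
        coding += sum(e - s for s, e in ivs)
    return coding, percentage(coding, size)


def cog_distribution(assignments, protein_genes: int) -> pd.DataFrame:
    """Gene counts and percentages per COG functional category.

    A gene with k category letters increments k categories. The trailing
    "_" row counts protein-coding genes absent from the table ("not in
    COGs"). Percentages are over ``protein_genes`` and rounded to 2 dp.
    """
    assignments = list(assignments)
    assigned = {a.gene_id for a in assignments}
    if protein_genes < len(assigned):
        raise ValueError("protein_genes smaller than the number of assigned genes")
    counts = {c: 0 for c in COG_CATEGORIES}
    for a in assignments:
        if not isinstance(a, CogAssignment):
            a = CogAssignment(*a)
        for c in a.categories:
            counts[c] += 1
    rows = [
        {
            "category": c,
            "count": counts[c],
            "pct": round(percentage(counts[c], protein_genes), 2),
            "description": COG_NAMES[c],
        }
        for c in COG_CATEGORIES
    ]
    rows.append(
        {
            "category": "_",
            "count": protein_genes - len(assigned),
            "pct": round(percentage(protein_genes - len(assigned), protein_genes), 2),
            "description": "Not in COGs",
        }
    )
    return pd.DataFrame(rows)


def delineation_check(identity_pct: float, policy: DelineationPolicy | None = None) -> str:
    """Species-delineation verdict from a 16S rRNA identity percentage.

    Strictly below the threshold flags a candidate new species; at or
    above it the isolate falls within a known species.
    """
    policy = policy or DelineationPolicy()
    if not 0 <= identity_pct <= 100:
        raise ValueError("identity_pct outside [0, 100]")
    if identity_pct < policy.threshold_pct:
        return "candidate new species"
    return "within known species"
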