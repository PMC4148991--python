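"""Reciprocal-best-hit orthology and the AGIOS statistic.

Orthologous gene pairs between two genomes are detected as reciprocal
best hits (RBH) on the protein level: each protein's best-scoring
global alignment partner in the other genome, kept only when the choice
is mutual and the pair passes minimum-identity and minimum-coverage
filters. AGIOS (Average Genomic Identity Of gene Sequences) is then the
unweighted mean percent nucleotide identity of the corresponding CDS
pairs under the same global aligner — an ANI-like statistic restricted
to genic regions.

A shared-k-mer prefilter (default k = 5 on the protein alphabet) skips
candidate pairs without any common k-mer; it is a speed device only and
can be disabled, which must not change results on realistic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from agios.align import (
    ScoringScheme,
    alignment_score,
    global_align,
    percent_identity,
)
from agios.seqio import GeneSet


@dataclass(frozen=True)
class RbhParams:
    """Thresholds for reciprocal-best-hit ortholog detection."""

    min_pct_identity: float = 30.0
    min_coverage: float = 0.5
    prefilter_kmer: int | None = 5

    def __post_init__(self):
        if not 0 <= self.min_pct_identity <= 100:
            raise ValueError("min_pct_identity outside [0, 100]")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage outside (0, 1]")
        if self.prefilter_kmer is not None and self.prefilter_kmer < 3:
            raise ValueError("prefilter_kmer must be >= 3 (or None to disable)")


@dataclass(frozen=True)
class OrthologPair:
    """One RBH gene pair with protein- and nucleotide-level identities."""

    gene_a: str
    gene_b: str
    protein_identity: float
    nucleotide_identity: float | None = None

    def __post_init__(self):
        for v in (self.protein_identity, self.nucleotide_identity):
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"identity {v} outside [0, 100]")


@dataclass
class AgiosResult:
    """Per-genome-pair AGIOS summary.

    ``agios`` is None (missing, not zero) when no orthologs were found.
    ``agios_length_weighted`` weights each pair by its nucleotide
    alignment length; the headline statistic is the unweighted mean.
    """

    genome_a: str
    genome_b: str
    per_pair: list
    agios: float | None
    agios_length_weighted: float | None = None

    @property
    def n_orthologs(self) -> int:
        return len(self.per_pair)


@dataclass
class AgiosMatrix:
    """Multi-genome comparison grid: diagonal gene counts, upper-triangle
    ortholog counts, lower-triangle AGIOS percentages."""

    labels: list
    gene_counts: dict
    ortholog_counts: dict  # frozenset({a, b}) -> int
    agios_values: dict  # frozenset({a, b}) -> float | None
    results: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Render the comparison grid as a DataFrame in the conventional
        layout (gene counts on the diagonal, shared-ortholog counts above,
        AGIOS percentages below)."""
        k = len(self.labels)
        grid = [["" for _ in range(k)] for _ in range(k)]
        for i, la in enumerate(self.labels):
            grid[i][i] = str(self.gene_counts[la])
            for j in range(i + 1, k):
                lb = self.labels[j]
                key = frozenset((la, lb))
                grid[i][j] = str(self.ortholog_counts[key])
                v = self.agios_values[key]
                grid[j][i] = "NA" if v is None else f"{v:.2f}"
        return pd.DataFrame(grid, index=self.labels, columns=self.labels)


def _kmer_candidates(prot_a: list, prot_b: list, k: int) -> list:
    """Indices (i, j) of protein pairs sharing at least one k-mer."""
    index: dict[str, list[int]] = {}
    for j, p in enumerate(prot_b):
        seen = set()
        s = p.residues
        for pos in range(len(s) - k + 1):
            seen.add(s[pos:pos + k])
        for kmer in seen:
            index.setdefault(kmer, []).append(j)
    out = []
    for i, p in enumerate(prot_a):
        s = p.residues
        hits: set[int] = set()
        for pos in range(len(s) - k + 1):
            hits.update(index.get(s[pos:pos + k], ()))
        out.extend((i, j) for j in sorted(hits))
    return out


def _best_hits(ids_a, ids_b, scores: dict) -> dict:
    """Best subject in B for each query in A: higher score, then
    lexicographically smaller subject id."""
    best: dict[str, str] = {}
    for qa in ids_a:
        cand = [(sb, scores[(qa, sb)]) for sb in ids_b if (qa, sb) in scores]
        if not cand:
            continue
        top = max(s for _, s in cand)
        best[qa] = min(sb for sb, s in cand if s == top)
    return best


def detect_orthologs(
    set_a: GeneSet,
    set_b: GeneSet,
    params: RbhParams | None = None,
    scoring: ScoringScheme | None = None,
) -> list:
    """Reciprocal-best-hit ortholog pairs between two gene sets.

    Proteins are translated from CDS where not supplied. Best hits use
    the affine-gap global protein alignment score; mutual best hits are
    kept when percent identity >= ``min_pct_identity`` and the aligned
    (non-gap) columns cover >= ``min_coverage`` of the shorter protein.
    Output is sorted by gene_a id; each gene appears in at most one pair.
    """
    params = params or RbhParams()
    scoring = scoring or ScoringScheme.protein_default()
    prot_a = set_a.translated()
    prot_b = set_b.translated()
    if not prot_a or not prot_b:
        empty = set_a.genome_label if not prot_a else set_b.genome_label
        raise ValueError(f"gene set {empty!r} has no translatable CDS and no proteins")
    ids_a = sorted(prot_a)
    ids_b = sorted(prot_b)
    recs_a = [prot_a[i] for i in ids_a]
    recs_b = [prot_b[i] for i in ids_b]

    if params.prefilter_kmer:
        cand = _kmer_candidates(recs_a, recs_b, params.prefilter_kmer)
    else:
        cand = [(i, j) for i in range(len(ids_a)) for j in range(len(ids_b))]

    scores: dict[tuple, float] = {}
    for i, j in cand:
        scores[(ids_a[i], ids_b[j])] = alignment_score(recs_a[i], recs_b[j], scoring)

    best_ab = _best_hits(ids_a, ids_b, scores)
    scores_rev = {(sb, qa): s for (qa, sb), s in scores.items()}
    best_ba = _best_hits(ids_b, ids_a, scores_rev)

    pairs = []
    for qa, sb in best_ab.items():
        if best_ba.get(sb) != qa:
            continue
        aln = global_align(prot_a[qa], prot_b[sb], scoring)
        ident = percent_identity(aln)
        aligned_cols = aln.n_matches + aln.n_mismatches
        shorter = min(len(prot_a[qa]), len(prot_b[sb]))
        if ident < params.min_pct_identity:
            continue
        if aligned_cols / shorter < params.min_coverage:
            continue
        pairs.append(OrthologPair(qa, sb, protein_identity=ident))
    return sorted(pairs, key=lambda p: p.gene_a)


def compute_agios(
    set_a: GeneSet,
    set_b: GeneSet,
    params: RbhParams | None = None,
    scoring: ScoringScheme | None = None,
    nt_scoring: ScoringScheme | None = None,
) -> AgiosResult:
    """AGIOS between two gene sets: mean nucleotide identity over RBH pairs.

    For every ortholog pair the nucleotide CDS pair is globally aligned
    and its percent identity (all columns in the denominator) recorded;
    AGIOS is the unweighted mean. With zero orthologs AGIOS is missing
    (None), never 0.
    """
    nt_scoring = nt_scoring or ScoringScheme.nucleotide_default()
    pairs = detect_orthologs(set_a, set_b, params, scoring)
    genes_a = {g.id: g for g in set_a.genes}
    genes_b = {g.id: g for g in set_b.genes}
    done = []
    lengths = []
    for p in pairs:
        aln = global_align(genes_a[p.gene_a], genes_b[p.gene_b], nt_scoring)
        done.append(
            OrthologPair(
                p.gene_a,
                p.gene_b,
                protein_identity=p.protein_identity,
                nucleotide_identity=percent_identity(aln),
            )
        )
        lengths.append(aln.length)
    if done:
        idents = np.array([p.nucleotide_identity for p in done])
        agios = float(idents.mean())
        weighted = float(np.average(idents, weights=np.array(lengths)))
    else:
        agios = weighted = None
    return AgiosResult(
        genome_a=set_a.genome_label,
        genome_b=set_b.genome_label,
        per_pair=done,
        agios=agios,
        agios_length_weighted=weighted,
    )


def agios_matrix(
    genomes: list,
    params: RbhParams | None = None,
    scoring: ScoringScheme | None = None,
    nt_scoring: ScoringScheme | None = None,
) -> AgiosMatrix:
    """All-pairs AGIOS comparison over two or more gene sets."""
    labels = [g.genome_label for g in genomes]
    if len(labels) < 2:
        raise ValueError("need at least 2 genomes for a comparison matrix")
    if len(set(labels)) != len(labels):
        raise ValueError("genome labels must be unique")
    gene_counts = {g.genome_label: g.gene_count for g in genomes}
    ortho: dict = {}
    values: dict = {}
    results: dict = {}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            res = compute_agios(genomes[i], genomes[j], params, scoring, nt_scoring)
            key = frozenset((labels[i], labels[j]))
            ortho[key] = res.n_orthologs
            values[key] = res.agios
            results[key] = res
    return AgiosMatrix(labels, gene_counts, ortho, values, results)


def per_pair_frame(result: AgiosResult) -> pd.DataFrame:
    """Ortholog-pair detail table: gene_a, gene_b, protein_identity,
    nucleotide_identity."""
    return pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "protein_identity": p.protein_identity,
                "nucleotide_identity": p.nucleotide_identity,
            }
            for p in result.per_pair
        ],
        columns=["gene_a", "gene_b", "protein_identity", "nucleotide_identity"],
    )
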