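# Methods

## The statistic

AGIOS (Average Genomic Identity Of gene Sequences) measures relatedness
between two annotated genomes through their genes only. Orthologous gene
pairs are detected on the protein level, the corresponding nucleotide
CDS are globally aligned, and AGIOS is the unweighted arithmetic mean of
the per-pair percent nucleotide identities. It is an ANI-like statistic
restricted to genic regions: intergenic sequence, rearrangement and gene
order play no role. With zero detected orthologs the statistic is
reported as missing, never as zero. A length-weighted mean is computed
alongside (each pair weighted by its alignment length) but the headline
value is the unweighted mean, because the statistic is defined per
orthologous gene, not per base.

## Alignment model

Global Needleman-Wunsch with affine gaps: three dynamic-programming
states (substitution M, gap-in-b Ix, gap-in-a Iy), end gaps penalized,
a gap of length L costing `gap_open + L * gap_extend`. Defaults, all
overridable:

| parameter | nucleotide | protein |
|---|---|---|
| match / mismatch | +5 / −4 | BLOSUM62 |
| gap open | 10 | 11 |
| gap extend | 0.5 | 1 |

These are the familiar megablast- and blastp-style settings, chosen as
documented, reproducible defaults; AGIOS values do shift a little under
other reasonable schemes, which is why the scheme is part of the run
configuration and logged with every run.

Percent identity is `100 × matches / alignment columns`, counting
internal **and terminal** gap columns in the denominator — the most
conservative convention. Because published identity values do not always
state their denominator, `percent_identity(aln,
include_terminal_gaps=False)` exposes the alternative; both appear in
the CLI `align` output. Ambiguous residues (N and other IUPAC codes; X
for proteins) are accepted on input but never count as matches, and
score as mismatches — conservative and deterministic.

Determinism: traceback prefers diagonal over up (gap in b) over left
(gap in a) on ties, and predecessor-state ties resolve M > Ix > Iy, so
identical inputs give byte-identical alignments on any platform. The DP
inner loops are numba-compiled; the reference algorithm is implemented
here in full and tested against (i) exhaustive enumeration of all
global alignments for short pairs and (ii) Biopython's independent
PairwiseAligner on random longer pairs.

## Orthology

Plain reciprocal best hits: each protein's best partner in the other
genome by global-alignment score (ties broken toward the
lexicographically smaller id), kept when mutual. Accepted pairs must
show ≥ 30% identity and aligned (non-gap) columns covering ≥ 50% of the
shorter protein. RBH is the core criterion of the standard orthology
tools; their graph-clustering refinements (paralog groups, synteny) are
deliberately out of scope, so each gene appears in at most one pair.
Scoring uses the global affine-gap score rather than a local-alignment
bit score — a documented deviation from BLAST-based RBH that keeps the
package self-contained and oracle-verified.

A shared-k-mer prefilter (k = 5, protein alphabet) skips pairs with no
common k-mer before any alignment. It is purely a speed device: tests
assert that disabling it leaves results unchanged on the fixtures.
Genes whose CDS fails translation (internal stop, length not a multiple
of three) are excluded from RBH but still counted in the per-genome
gene totals shown on the matrix diagonal.

## ORFan rule

A gene is an ORFan when no similarity hit qualifies as homology
evidence. A hit qualifies when E ≤ 1e-3 with alignment length > 80 aa,
or E ≤ 1e-5 with length ≤ 80 aa. Three boundary decisions, all
deterministic and documented: exactly 80 aa routes to the stricter
short branch; E-value comparisons are inclusive; self-hits (query id =
subject id) never count. The `literal_rule` flag inverts the predicate
(ORFan = *has* a below-threshold hit) for replicating texts whose
wording states the rule that way; the conventional reading is the
default because it is the only one under which ORFans are the small
minority they are universally reported to be.

## Genome summaries

G+C counts G, C and the ambiguity code S (G-or-C) in the numerator and
every residue, N included, in the denominator. Coding density merges
overlapping gene intervals (0-based half-open) before counting covered
bases, verified against a per-base boolean-mask oracle. COG percentages
use the protein-coding gene count as denominator; a gene with k
category letters increments k categories, so category counts can sum to
more than the gene total — the table reports counts and percentages so
both conventions are recoverable. The species-delineation verdict is
strict: identity strictly below the threshold (default 98.7%) flags a
candidate new species; exactly at the threshold does not.

## Simulator

The generator emulates the regime these statistics are used in: two (or
more) bacterial gene sets descended from a common ancestor. Ancestor
genes are drawn codon-wise from the 61 sense codons with codon weights
that are products of base probabilities tuned to a G+C target
(default 0.62, typical of high-GC Actinobacteria); lengths are uniform
over 100–500 codons; defaults are 200 genes per genome. Descendant B
substitutes each site independently with probability d to a uniformly
chosen different base (Jukes-Cantor-like), redrawing any substitution
that would create an internal stop codon; descendant A is the ancestor
itself. Optional independent per-gene loss (probability per descendant)
and a single codon-length indel per gene are available; CDS carry no
trailing stop codon, which `translate_cds` treats as optional.

The truth table records **realized** identity — the exact fraction of
unchanged sites between the two copies — rather than the nominal d, so
recovery tests compare the estimator to the actual simulated signal
with no Monte-Carlo slack. With indels enabled, realized identity is
bookkept over the substitution step only. Gene ids encode ancestry
(`anc0007_A` / `anc0007_B`), making ortholog recovery checkable by id
without alignment. A site-wise substitution model was chosen over codon
models because AGIOS is an identity statistic, not a selection
statistic; what matters is exact bookkeeping, not realistic dN/dS.

What the simulator does **not** emulate: intergenic sequence, operon
structure, rearrangement, horizontal transfer, rate heterogeneity
across sites or genes, and realistic rRNA evolution. Passing recovery
tests therefore demonstrates that the estimator chain (translation →
RBH → alignment → averaging) is unbiased and exact under the stated
divergence model; it does not certify behaviour on real genomes with
paralogy, mosaicism or annotation error.

## Problem sizes and numerics

Recovery tests run 200-gene genomes at divergences 0.01–0.20 with three
seeds each, the scale at which the mean realized identity is determined
to well under the 0.5-point recovery tolerance; alignment-oracle sweeps
use ≥ 500 random pairs of length ≤ 8 where exhaustive enumeration is
exact. AGIOS's mean is validated to 1e-9 against its per-pair values;
all percentage roundings are half-even to 2 dp at report boundaries
only, never internally. Degenerate inputs are hard errors rather than
silent defaults: empty sequences, empty gene sets, zero-ortholog AGIOS
(missing, not 0), empty gene lists for the ORFan rule.

## Known limitations

- RBH under global-alignment score can mis-rank partners for proteins
  with large length differences, where a local score would not penalize
  the unaligned tail; the coverage filter bounds but does not eliminate
  this.
- The k-mer prefilter is heuristic; at very high divergence (> ~40%
  protein distance) it could in principle drop a true best hit. At the
  divergences where AGIOS is informative this does not occur.
- AGIOS depends on the annotation: differing gene calls between two
  genomes shift both the ortholog count and the mean.
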