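"""Synthetic genome-pair generator with exact ground truth.

Emulates pairs (or stars) of bacterial gene sets descended from a
common ancestor: ancestor CDS are drawn codon-wise from the 61 non-stop
codons with base composition tuned to a G+C target, and each descendant
accumulates site-wise substitutions with a per-site probability d
(Jukes-Cantor-like: a mutated site takes one of the three other bases
uniformly; any substitution creating an internal stop codon is redrawn
among the non-ancestral bases). Optional per-gene loss and a single
codon-length indel per gene are supported.

The truth table records REALIZED identity — the exact fraction of sites
left unchanged between the two descendants' copies — not the nominal d,
so downstream recovery tests carry no Monte-Carlo slack. Gene ids
encode ancestry (``anc0007_A`` / ``anc0007_B``), making orthology
recovery checkable by id alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from agios.seqio import GeneSet, SequenceRecord, translate_cds, write_fasta

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
#: The 61 sense codons of the bacterial genetic code.
SENSE_CODONS = tuple(
    "".join(c) for c in product(_BASES, repeat=3) if "".join(c) not in _STOPS
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated descendant pair.

    ``divergence_d`` is the per-site substitution probability applied to
    descendant B; descendant A is an unmutated copy of the ancestor.
    ``gc_target`` tunes the ancestor's base composition (achieved within
    about two percentage points; stop-codon exclusion shifts it slightly).
    """

    n_genes: int = 200
    gene_length_range: tuple = (100, 500)  # codons
    gc_target: float = 0.62
    divergence_d: float = 0.05
    p_gene_loss: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if not (30 <= lo <= hi):
            raise ValueError("gene lengths must be >= 30 codons and ordered")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if not 0 <= self.divergence_d <= 0.75:
            raise ValueError("divergence_d outside [0, 0.75]")
        if not 0 <= self.p_gene_loss < 1:
            raise ValueError("p_gene_loss outside [0, 1)")
        if not 0 <= self.indel_rate <= 1:
            raise ValueError("indel_rate outside [0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated pair.

    ``per_gene_realized_identity`` maps ancestor gene id to the percent
    of sites unchanged between the two descendants' copies (substitution
    sites only; indels are excluded from the bookkeeping).
    """

    shared_gene_ids: frozenset
    present_in_a: frozenset
    present_in_b: frozenset
    per_gene_realized_identity: dict
    seed: int

    @property
    def mean_realized_identity(self) -> float:
        vals = [self.per_gene_realized_identity[g] for g in sorted(self.shared_gene_ids)]
        return float(np.mean(vals))


def _codon_distribution(gc_target: float) -> np.ndarray:
    p = {
        "G": gc_target / 2,
        "C": gc_target / 2,
        "A": (1 - gc_target) / 2,
        "T": (1 - gc_target) / 2,
    }
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in SENSE_CODONS])
    total = w.sum()
    if total <= 0:
        raise ValueError(f"gc_target {gc_target} admits no sense codons")
    return w / total


def _draw_ancestor(config: SimulationConfig, rng: np.random.Generator) -> list:
    """Ancestor CDS as strings (no trailing stop codon)."""
    probs = _codon_distribution(config.gc_target)
    lo, hi = config.gene_length_range
    genes = []
    for _ in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=probs)
        genes.append("".join(SENSE_CODONS[i] for i in idx))
    return genes


def _mutate(seq: str, d: float, rng: np.random.Generator) -> tuple:
    """Site-wise substitution with stop avoidance.

    Returns (mutated sequence, number of substituted sites). Every
    masked site ends up different from the ancestral base, so the
    substitution count is exact.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    base_idx = np.zeros(arr.size, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_idx[arr == ord(b)] = i
    mask = rng.random(arr.size) < d
    if not mask.any():
        return seq, 0
    shift = rng.integers(1, 4, size=int(mask.sum()))
    new_idx = base_idx.copy()
    new_idx[mask] = (base_idx[mask] + shift) % 4
    # redraw any mutated codon that became a stop
    for c0 in range(0, arr.size, 3):
        if not mask[c0:c0 + 3].any():
            continue
        guard = 0
        while "".join(_BASES[i] for i in new_idx[c0:c0 + 3]) in _STOPS:
            for s in range(c0, c0 + 3):
                if mask[s]:
                    new_idx[s] = (base_idx[s] + rng.integers(1, 4)) % 4
            guard += 1
            if guard > 100:  # cannot happen: <=2 stops share two fixed bases
                raise RuntimeError("stop-avoidance redraw did not converge")
    out = "".join(_BASES[i] for i in new_idx)
    return out, int(mask.sum())


def _apply_indel(seq: str, rng: np.random.Generator, probs: np.ndarray) -> str:
    """Insert or delete one codon at a random codon boundary."""
    n_codons = len(seq) // 3
    if rng.random() < 0.5 and n_codons > 30:
        k = int(rng.integers(0, n_codons))
        return seq[: 3 * k] + seq[3 * (k + 1):]
    k = int(rng.integers(0, n_codons + 1))
    codon = SENSE_CODONS[int(rng.choice(len(SENSE_CODONS), p=probs))]
    return seq[: 3 * k] + codon + seq[3 * k:]


def _gene_id(i: int) -> str:
    return f"anc{i:04d}"


def _make_gene_set(label: str, genes: dict) -> GeneSet:
    records = [
        SequenceRecord(f"{gid}_{label}", seq, alphabet="nucleotide")
        for gid, seq in sorted(genes.items())
    ]
    return GeneSet(genome_label=label, genes=records)


def simulate_pair(config: SimulationConfig | None = None):
    """Simulate one descendant pair (A = ancestor copy, B = mutated).

    Returns ``(gene_set_a, gene_set_b, truth)``. Fully reproducible from
    ``config.seed``; all emitted CDS translate cleanly (no internal
    stops, lengths multiples of three).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    ancestor = _draw_ancestor(config, rng)
    probs = _codon_distribution(config.gc_target)

    genes_a: dict[str, str] = {}
    genes_b: dict[str, str] = {}
    identity: dict[str, float] = {}
    for i, anc in enumerate(ancestor):
        gid = _gene_id(i)
        mutated, n_sub = _mutate(anc, config.divergence_d, rng)
        identity[gid] = 100.0 * (1 - n_sub / len(anc))
        lost_a = rng.random() < config.p_gene_loss
        lost_b = rng.random() < config.p_gene_loss
        if config.indel_rate and rng.random() < config.indel_rate:
            mutated = _apply_indel(mutated, rng, probs)
        if not lost_a:
            genes_a[gid] = anc
        if not lost_b:
            genes_b[gid] = mutated
    shared = frozenset(genes_a) & frozenset(genes_b)
    truth = SimulationTruth(
        shared_gene_ids=frozenset(shared),
        present_in_a=frozenset(genes_a),
        present_in_b=frozenset(genes_b),
        per_gene_realized_identity=identity,
        seed=config.seed,
    )
    return _make_gene_set("A", genes_a), _make_gene_set("B", genes_b), truth


def simulate_star(
    config: SimulationConfig,
    divergences: dict,
    p_gene_loss: float | None = None,
):
    """Simulate >= 2 descendants radiating from one shared ancestor.

    ``divergences`` maps descendant label -> per-site divergence from
    the ancestor. Returns ``(gene_sets, pairwise_identity)`` where
    ``gene_sets`` maps label -> GeneSet and ``pairwise_identity`` maps
    ``frozenset({la, lb})`` -> mean percent of unchanged sites between
    the two descendants over their shared genes (computed directly from
    the sequences). Indels are not supported in star mode.
    """
    if len(divergences) < 2:
        raise ValueError("star simulation needs >= 2 descendants")
    if config.indel_rate:
        raise ValueError("indels are not supported in star mode")
    loss = config.p_gene_loss if p_gene_loss is None else p_gene_loss
    rng = np.random.default_rng(config.seed)
    ancestor = _draw_ancestor(config, rng)

    per_label: dict[str, dict[str, str]] = {}
    for label in sorted(divergences):
        d = divergences[label]
        genes: dict[str, str] = {}
        for i, anc in enumerate(ancestor):
            mutated, _ = _mutate(anc, d, rng)
            if rng.random() >= loss:
                genes[_gene_id(i)] = mutated
        per_label[label] = genes

    labels = sorted(divergences)
    pairwise: dict[frozenset, float] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            la, lb = labels[i], labels[j]
            shared = sorted(set(per_label[la]) & set(per_label[lb]))
            idents = []
            for gid in shared:
                x, y = per_label[la][gid], per_label[lb][gid]
                same = sum(1 for u, v in zip(x, y) if u == v)
                idents.append(100.0 * same / len(x))
            pairwise[frozenset((la, lb))] = float(np.mean(idents)) if idents else float("nan")

    gene_sets = {label: _make_gene_set(label, per_label[label]) for label in labels}
    return gene_sets, pairwise


def write_pair_outputs(out_dir, set_a: GeneSet, set_b: GeneSet, truth: SimulationTruth):
    """Write A/B gene sets as .ffn/.faa FASTA plus the truth table.

    truth.tsv columns: gene_id, present_in_A, present_in_B,
    realized_identity_pct (percent of unchanged sites; blank for genes
    lost from either descendant).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for gs in (set_a, set_b):
        label = gs.genome_label
        ffn = out_dir / f"{label}.ffn"
        write_fasta(gs.genes, ffn)
        faa = out_dir / f"{label}.faa"
        write_fasta([translate_cds(g) for g in gs.genes], faa)
        paths[f"{label}.ffn"] = ffn
        paths[f"{label}.faa"] = faa
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "wt") as fh:
        fh.write("gene_id\tpresent_in_A\tpresent_in_B\trealized_identity_pct\n")
        all_ids = sorted(set(truth.present_in_a) | set(truth.present_in_b))
        for gid in all_ids:
            in_a = gid in truth.present_in_a
            in_b = gid in truth.present_in_b
            ident = (
                f"{truth.per_gene_realized_identity[gid]:.6f}" if in_a and in_b else ""
            )
            fh.write(f"{gid}\t{int(in_a)}\t{int(in_b)}\t{ident}\n")
    paths["truth.tsv"] = truth_path
    return paths
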