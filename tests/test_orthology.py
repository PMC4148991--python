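import numpy as np
import pytest

from agios.orthology import (
    RbhParams,
    agios_matrix,
    compute_agios,
    detect_orthologs,
    per_pair_frame,
)
from agios.seqio import GeneSet, SequenceRecord
from agios.simulate import SimulationConfig, simulate_pair, simulate_star
from conftest import random_gene_set


def relabel(gs: GeneSet, label: str) -> GeneSet:
    genes = [
        SequenceRecord(g.id.replace(gs.genome_label, label, 1), g.residues)
        for g in gs.genes
    ]
    return GeneSet(genome_label=label, genes=genes)


def ancestor_ids(pairs, which: str):
    idx = 0 if which == "a" else 1
    return {getattr(p, f"gene_{which}").rsplit("_", 1)[0] for p in pairs}


class TestDetectOrthologs:
    def test_self_comparison_recovers_everything(self, small_gene_set):
        other = relabel(small_gene_set, "Y")
        pairs = detect_orthologs(small_gene_set, other)
        assert len(pairs) == small_gene_set.gene_count
        assert all(p.protein_identity == pytest.approx(100.0) for p in pairs)
        # RBH is a matching: no gene twice
        assert len({p.gene_a for p in pairs}) == len(pairs)
        assert len({p.gene_b for p in pairs}) == len(pairs)

    def test_unrelated_proteins_give_no_pairs(self, rng):
        a = random_gene_set(rng, "A", n_genes=20, n_codons=100)
        b = random_gene_set(rng, "B", n_genes=20, n_codons=100)
        assert detect_orthologs(a, b) == []

    def test_output_sorted_by_gene_a(self, rng):
        a = random_gene_set(rng, "A", n_genes=6, n_codons=40)
        pairs = detect_orthologs(a, relabel(a, "B"))
        assert [p.gene_a for p in pairs] == sorted(p.gene_a for p in pairs)

    def test_prefilter_is_transparent(self):
        a, b, _ = simulate_pair(SimulationConfig(n_genes=15, divergence_d=0.1, seed=4,
                                                 gene_length_range=(40, 80)))
        with_filter = detect_orthologs(a, b, RbhParams(prefilter_kmer=5))
        without = detect_orthologs(a, b, RbhParams(prefilter_kmer=None))
        assert with_filter == without

    def test_empty_gene_set_error(self, small_gene_set):
        bad = GeneSet("Z", genes=[SequenceRecord("z1", "ATGTAAGCT")])  # untranslatable
        with pytest.raises(ValueError, match="no translatable"):
            detect_orthologs(small_gene_set, bad)


class TestComputeAgios:
    def test_genome_vs_itself_is_100(self, small_gene_set):
        res = compute_agios(small_gene_set, relabel(small_gene_set, "Y"))
        assert res.agios == pytest.approx(100.0)
        assert res.n_orthologs == small_gene_set.gene_count

    def test_mean_matches_per_pair_values(self):
        a, b, _ = simulate_pair(SimulationConfig(n_genes=12, divergence_d=0.08, seed=9,
                                                 gene_length_range=(40, 80)))
        res = compute_agios(a, b)
        idents = [p.nucleotide_identity for p in res.per_pair]
        assert res.agios == pytest.approx(np.mean(idents), abs=1e-9)
        assert 0 <= res.agios <= 100
        assert res.n_orthologs <= min(a.gene_count, b.gene_count)

    def test_symmetry(self):
        a, b, _ = simulate_pair(SimulationConfig(n_genes=10, divergence_d=0.1, seed=2,
                                                 gene_length_range=(40, 80)))
        ab = compute_agios(a, b)
        ba = compute_agios(b, a)
        assert ab.n_orthologs == ba.n_orthologs
        assert ab.agios == pytest.approx(ba.agios)
        assert {(p.gene_a, p.gene_b) for p in ab.per_pair} == {
            (p.gene_b, p.gene_a) for p in ba.per_pair
        }

    def test_zero_orthologs_reports_missing(self, rng):
        a = random_gene_set(rng, "A", n_genes=5, n_codons=80)
        b = random_gene_set(rng, "B", n_genes=5, n_codons=80)
        res = compute_agios(a, b)
        assert res.n_orthologs == 0
        assert res.agios is None  # missing, not 0

    def test_recovery_on_simulated_pair(self):
        cfg = SimulationConfig(n_genes=50, divergence_d=0.05, seed=1)
        a, b, truth = simulate_pair(cfg)
        res = compute_agios(a, b)
        assert ancestor_ids(res.per_pair, "a") == set(truth.shared_gene_ids)
        assert abs(res.agios - truth.mean_realized_identity) <= 0.5


class TestAgiosMatrix:
    def test_three_identical_genomes(self, small_gene_set):
        gs = [relabel(small_gene_set, l) for l in ("A", "B", "C")]
        m = agios_matrix(gs)
        n = small_gene_set.gene_count
        for key in m.agios_values:
            assert m.agios_values[key] == pytest.approx(100.0)
            assert m.ortholog_counts[key] == n
        frame = m.to_frame()
        assert list(frame.index) == ["A", "B", "C"]
        assert frame.loc["A", "A"] == str(n)
        assert frame.loc["B", "A"] == "100.00"
        assert frame.loc["A", "B"] == str(n)

    def test_matrix_consistent_with_pairwise(self):
        sets, _ = simulate_star(
            SimulationConfig(n_genes=10, seed=6, gene_length_range=(40, 70)),
            divergences={"A": 0.02, "B": 0.05, "C": 0.1},
        )
        genomes = [sets[l] for l in "ABC"]
        m = agios_matrix(genomes)
        for i in range(3):
            for j in range(i + 1, 3):
                res = compute_agios(genomes[i], genomes[j])
                key = frozenset((genomes[i].genome_label, genomes[j].genome_label))
                assert m.agios_values[key] == pytest.approx(res.agios)
                assert m.ortholog_counts[key] == res.n_orthologs

    def test_star_ordering_follows_divergence(self):
        sets, truth_pairwise = simulate_star(
            SimulationConfig(n_genes=30, seed=8, gene_length_range=(60, 120)),
            divergences={"N": 0.02, "M": 0.05, "F": 0.10},
        )
        m = agios_matrix([sets[l] for l in sorted(sets)])
        # closer pairs score higher, matching the simulator's own bookkeeping
        order_agios = sorted(m.agios_values, key=lambda k: m.agios_values[k])
        order_truth = sorted(truth_pairwise, key=lambda k: truth_pairwise[k])
        assert order_agios == order_truth

    def test_duplicate_labels_rejected(self, small_gene_set):
        with pytest.raises(ValueError, match="unique"):
            agios_matrix([small_gene_set, small_gene_set])

    def test_needs_two_genomes(self, small_gene_set):
        with pytest.raises(ValueError, match="at least 2"):
            agios_matrix([small_gene_set])


def test_per_pair_frame_columns(small_gene_set):
    res = compute_agios(small_gene_set, relabel(small_gene_set, "Y"))
    frame = per_pair_frame(res)
    assert list(frame.columns) == [
        "gene_a", "gene_b", "protein_identity", "nucleotide_identity",
    ]
    assert len(frame) == res.n_orthologs
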