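"""End-to-end comparison pipeline and run configuration.

``run_pipeline`` loads two or more gene sets, computes the all-pairs
AGIOS matrix, and writes a tab-separated matrix in the conventional
grid layout (diagonal gene counts, upper-triangle ortholog counts,
lower-triangle AGIOS), one per-pair ortholog detail table per
comparison, and a JSON summary. Output is a pure function of (inputs,
config, seed): two identical runs produce byte-identical files.

Run configuration is a flat key=value text file mirrored one-to-one by
CLI flags; explicitly passed flags win over the file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from agios.align import ScoringScheme
from agios.orthology import RbhParams, agios_matrix, per_pair_frame
from agios.seqio import GeneSet, read_fasta

log = logging.getLogger("agios")

#: keys accepted in a run-config file, with their parsers
_CONFIG_KEYS = {
    "min_identity": float,
    "min_coverage": float,
    "prefilter_kmer": int,
    "nt_match": float,
    "nt_mismatch": float,
    "nt_gap_open": float,
    "nt_gap_extend": float,
    "aa_gap_open": float,
    "aa_gap_extend": float,
    "substitution_matrix": str,
    "delineation_threshold": float,
    "out_dir": str,
    "log_level": str,
    "seed": int,
}


@dataclass
class RunConfig:
    """Resolved run settings; every override is validated by the owning
    parameter type before any computation starts."""

    min_identity: float = 30.0
    min_coverage: float = 0.5
    prefilter_kmer: int = 5
    nt_match: float = 5.0
    nt_mismatch: float = -4.0
    nt_gap_open: float = 10.0
    nt_gap_extend: float = 0.5
    aa_gap_open: float = 11.0
    aa_gap_extend: float = 1.0
    substitution_matrix: str = "BLOSUM62"
    delineation_threshold: float = 98.7
    out_dir: str = "agios_out"
    log_level: str = "INFO"
    seed: int = 0

    def rbh_params(self) -> RbhParams:
        return RbhParams(
            min_pct_identity=self.min_identity,
            min_coverage=self.min_coverage,
            prefilter_kmer=self.prefilter_kmer or None,
        )

    def nt_scoring(self) -> ScoringScheme:
        return ScoringScheme(
            mode="nucleotide",
            match=self.nt_match,
            mismatch=self.nt_mismatch,
            gap_open=self.nt_gap_open,
            gap_extend=self.nt_gap_extend,
        )

    def aa_scoring(self) -> ScoringScheme:
        return ScoringScheme(
            mode="protein",
            substitution_matrix=self.substitution_matrix,
            gap_open=self.aa_gap_open,
            gap_extend=self.aa_gap_extend,
        )


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional key=value file plus overrides.

    Unknown keys are hard errors; values passed as ``overrides`` (CLI
    flags) win over the file.
    """
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(open(path), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _CONFIG_KEYS[key](raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**values)
    # validate eagerly so a bad override fails before any computation
    cfg.rbh_params()
    cfg.nt_scoring()
    cfg.aa_scoring()
    return cfg


def load_gene_set(ffn_path, faa_path=None, label: str | None = None) -> GeneSet:
    """Load a gene set from a nucleotide CDS FASTA plus optional proteins."""
    ffn_path = Path(ffn_path)
    label = label or ffn_path.stem
    genes = read_fasta(ffn_path, alphabet="nucleotide")
    proteins = read_fasta(faa_path, alphabet="protein") if faa_path else None
    return GeneSet(genome_label=label, genes=genes, proteins=proteins)


def run_pipeline(config: RunConfig, gene_sets: list) -> dict:
    """Compute the AGIOS matrix over gene sets and write all reports.

    Returns a dict of output paths. Raises on unreadable inputs, invalid
    configuration, or fewer than two genomes.
    """
    if len(gene_sets) < 2:
        raise ValueError("matrix mode needs at least 2 genomes")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("resolved config: %s", config)

    matrix = agios_matrix(
        gene_sets,
        params=config.rbh_params(),
        scoring=config.aa_scoring(),
        nt_scoring=config.nt_scoring(),
    )
    paths: dict[str, Path] = {}
    matrix_path = out_dir / "agios_matrix.tsv"
    frame = matrix.to_frame()
    frame.to_csv(matrix_path, sep="\t")
    paths["matrix"] = matrix_path

    summary: dict = {"genomes": matrix.labels, "gene_counts": matrix.gene_counts, "pairs": []}
    for key, res in sorted(matrix.results.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        detail = per_pair_frame(res)
        detail_path = out_dir / f"pairs_{a}_vs_{b}.tsv"
        detail.to_csv(detail_path, sep="\t", index=False, float_format="%.6f")
        paths[f"pairs_{a}_vs_{b}"] = detail_path
        summary["pairs"].append(
            {
                "genome_a": a,
                "genome_b": b,
                "n_orthologs": res.n_orthologs,
                "agios": None if res.agios is None else round(res.agios, 6),
                "agios_length_weighted": (
                    None
                    if res.agios_length_weighted is None
                    else round(res.agios_length_weighted, 6)
                ),
            }
        )
    summary_path = out_dir / "summary.json"
    with open(summary_path, "wt") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = summary_path
    log.info("wrote %d report files to %s", len(paths), out_dir)
    return paths
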