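"""Dual-threshold ORFan classification from per-gene similarity hits.

An ORFan is a predicted protein-coding gene with no detectable homolog
in a reference database. The rule is length-dependent: a hit qualifies
as evidence of homology when its E-value is at or below 1e-3 for
alignment lengths greater than 80 amino acids, or at or below the
stricter 1e-5 for alignments of 80 amino acids or shorter. A gene with
no qualifying hit (including a gene with no hits at all) is an ORFan.

Self-hits (query id equal to subject id) are never counted as evidence.
The ``literal_rule`` switch inverts the predicate — a gene is then
called an ORFan when it HAS a hit below threshold — replicating a
wording occasionally seen in the literature; the conventional reading
is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from agios.seqio import HitRecord


@dataclass(frozen=True)
class OrfanPolicy:
    """Thresholds of the length-dependent ORFan rule."""

    e_long: float = 1e-3
    len_cut: int = 80
    e_short: float = 1e-5

    def __post_init__(self):
        if self.e_short > self.e_long:
            raise ValueError("e_short must be <= e_long")
        if self.len_cut < 1:
            raise ValueError("len_cut must be >= 1")


@dataclass
class OrfanReport:
    """Classification outcome over one gene set."""

    n_genes: int
    orfan_ids: frozenset

    @property
    def n_orfans(self) -> int:
        return len(self.orfan_ids)

    @property
    def fraction(self) -> float:
        """Percentage of genes classified as ORFans."""
        return 100.0 * self.n_orfans / self.n_genes


def qualifying_hit(hit: HitRecord, policy: OrfanPolicy | None = None) -> bool:
    """True when a hit counts as homology evidence under the policy.

    Alignments of exactly ``len_cut`` amino acids take the short
    (stricter) branch; E-value comparison is inclusive (<= threshold).
    """
    policy = policy or OrfanPolicy()
    if hit.aln_length > policy.len_cut:
        return hit.e_value <= policy.e_long
    return hit.e_value <= policy.e_short


def classify_orfans(
    gene_ids,
    hits,
    policy: OrfanPolicy | None = None,
    literal_rule: bool = False,
) -> OrfanReport:
    """Classify every gene as ORFan or not from its similarity hits.

    Hits whose query id is not in ``gene_ids`` are ignored with a
    warning; self-hits are ignored silently. Under the default rule a
    gene is an ORFan iff it has zero qualifying hits.
    """
    import warnings

    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids must be nonempty")
    known = set(gene_ids)
    policy = policy or OrfanPolicy()
    evidence: set[str] = set()
    for h in hits:
        if h.query_id not in known:
            warnings.warn(f"hit for unknown gene {h.query_id!r} ignored", stacklevel=2)
            continue
        if h.query_id == h.subject_id:
            continue
        if qualifying_hit(h, policy):
            evidence.add(h.query_id)
    if literal_rule:
        orfans = frozenset(evidence)
    else:
        orfans = frozenset(known - evidence)
    return OrfanReport(n_genes=len(gene_ids), orfan_ids=orfans)


def orfan_frame(gene_ids, hits, policy: OrfanPolicy | None = None) -> pd.DataFrame:
    """Per-gene detail table: gene_id, n_hits, n_qualifying, is_orfan."""
    policy = policy or OrfanPolicy()
    known = set(gene_ids)
    n_hits: dict[str, int] = {g: 0 for g in gene_ids}
    n_qual: dict[str, int] = {g: 0 for g in gene_ids}
    for h in hits:
        if h.query_id not in known or h.query_id == h.subject_id:
            continue
        n_hits[h.query_id] += 1
        if qualifying_hit(h, policy):
            n_qual[h.query_id] += 1
    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "n_hits": [n_hits[g] for g in gene_ids],
            "n_qualifying": [n_qual[g] for g in gene_ids],
            "is_orfan": [n_qual[g] == 0 for g in gene_ids],
        }
    )
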