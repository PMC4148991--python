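"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
the alignment oracle enumerates every global alignment recursively, and
the translation oracle is a direct codon-table lookup.
"""

from __future__ import annotations

import math


def brute_force_global_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Maximum global alignment score by exhaustive path enumeration.

    ``score(x, y)`` gives the substitution score; a gap run of length L
    costs ``gap_open + L * gap_extend``, charged again whenever a gap
    reopens (including switching which sequence is gapped). Only viable
    for short sequences.
    """
    best = -math.inf

    stack = [(0, 0, None, 0.0)]
    la, lb = len(a), len(b)
    while stack:
        i, j, prev, s = stack.pop()
        if i == la and j == lb:
            if s > best:
                best = s
            continue
        if i < la and j < lb:
            stack.append((i + 1, j + 1, "M", s + score(a[i], b[j])))
        if i < la:
            cost = gap_extend if prev == "U" else gap_open + gap_extend
            stack.append((i + 1, j, "U", s - cost))
        if j < lb:
            cost = gap_extend if prev == "L" else gap_open + gap_extend
            stack.append((i, j + 1, "L", s - cost))
    return best


def nucleotide_score(match: float = 5.0, mismatch: float = -4.0):
    def score(x: str, y: str) -> float:
        return match if (x == y and x in "ACGT") else mismatch

    return score


def translate_by_lookup(cds: str) -> str:
    """Direct bacterial-code codon lookup (table 11), no library call."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[11]
    aa = []
    for k in range(0, len(cds), 3):
        codon = cds[k:k + 3]
        if codon in table.stop_codons:
            aa.append("*")
        else:
            aa.append(table.forward_table[codon])
    return "".join(aa)
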