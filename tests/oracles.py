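"""Independent reference implementations used only to check the package.

These deliberately avoid the library's positional bookkeeping and
seeded search: the duplex oracle walks the alignment once and sums loop
and stack terms directly; the search oracle is a quadratic scan of
every window on both strands.
"""

from __future__ import annotations

import math
from typing import List, Tuple

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def whole_duplex_energy(guide_rna: str, protospacer: str, hybrid) -> float:
    """Total hybrid energy of a 20-bp guide/site duplex, no positional split.

    Direct translation of the scoring rules: Watson-Crick stacks for
    matched runs; per mismatch run, the available closing-stack mismatch
    terms plus the loop initiation penalty for twice the run length.
    """
    paired = protospacer.translate(str.maketrans("ACGT", "TGCA"))
    gd = guide_rna.replace("U", "T")
    match = [a == b for a, b in zip(gd, protospacer)]
    total = 0.0
    # matched stacks
    for i in range(19):
        if match[i] and match[i + 1]:
            total += hybrid.energy((guide_rna[i : i + 2], paired[i : i + 2]))
    # mismatch runs as interior loops
    i = 0
    while i < 20:
        if match[i]:
            i += 1
            continue
        j = i
        while j + 1 < 20 and not match[j + 1]:
            j += 1
        if i > 0:
            total += hybrid.energy((guide_rna[i - 1 : i + 1], paired[i - 1 : i + 1]))
        if j < 19:
            total += hybrid.energy((guide_rna[j : j + 2], paired[j : j + 2]))
        total += hybrid.loop_penalty(2 * (j - i + 1))
        i = j + 1
    return total


def dna_opening_energy(protospacer: str, dna_table) -> float:
    comp = protospacer.translate(str.maketrans("ACGT", "TGCA"))
    return sum(
        dna_table.energy((protospacer[i : i + 2], comp[i : i + 2])) for i in range(19)
    )


def pam_matches(pam: str, patterns) -> bool:
    return any(
        all(p == "N" or p == b for p, b in zip(pat, pam)) for pat in patterns
    )


def brute_force_search(
    genome_sequences, guide_dna: str, max_mismatches: int, pams
) -> List[Tuple[str, int, str, str, str, int]]:
    """Quadratic scan: (chrom, start, strand, protospacer, pam, mismatches)."""
    out = []
    for name, seq in genome_sequences.items():
        n = len(seq)
        for start in range(n - 22):
            window = seq[start : start + 23]
            if "N" in window:
                continue
            mm = sum(a != b for a, b in zip(guide_dna, window[:20]))
            if pam_matches(window[20:], pams) and mm <= max_mismatches:
                out.append((name, start, "+", window[:20], window[20:], mm))
            rc = revcomp(window)
            mm = sum(a != b for a, b in zip(guide_dna, rc[:20]))
            if pam_matches(rc[20:], pams) and mm <= max_mismatches:
                out.append((name, start, "-", rc[:20], rc[20:], mm))
    out.sort(key=lambda h: (h[0], h[1], h[2]))
    return out


def naive_specificity(dg_b_on: float, dg_b_others: List[float], beta: float) -> float:
    """CRISPRspec by direct exponential summation (no log-sum-exp)."""
    num = math.fsum(math.exp(-beta * d) for d in dg_b_others)
    den = num + math.exp(-beta * dg_b_on)
    return -math.log10(num / den)
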