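"""Guide–target duplex energetics.

Computes the position-resolved free-energy contributions of the 20-bp
gRNA–DNA hybrid, the Cas9-weighted hybridization energy ΔG_H, and the
DNA-opening penalty ΔG_O.

Positions are numbered 1..20 from the 5' end of the guide (PAM-distal)
to the PAM-proximal end; stack position i covers base pairs (i, i+1),
so a 20-bp duplex has 19 stacks.  Runs of consecutive matches contribute
per-stack Watson–Crick energies; each maximal mismatch run, together
with its closing stacks, is scored as one interior loop (closing-stack
mismatch terms plus a size-dependent loop initiation penalty) whose
total is divided equally over the stack positions it spans.  The sum of
the 19 positional contributions therefore equals the whole-duplex
energy exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .tables import DuplexKind, EnergyTable

__all__ = [
    "GuideRNA",
    "TargetSite",
    "PositionalContributions",
    "pairing_states",
    "positional_hybrid_contributions",
    "delta_g_h",
    "delta_g_o",
    "reverse_complement",
    "GUIDE_LENGTH",
    "N_STACKS",
]

logger = logging.getLogger(__name__)

GUIDE_LENGTH = 20
N_STACKS = GUIDE_LENGTH - 1
PAM_LENGTH = 3

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_FROM_DNA = str.maketrans("T", "U")


def reverse_complement(dna: str) -> str:
    """Reverse complement of a DNA string (uppercase, ACGTN)."""
    return dna.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class GuideRNA:
    """A 20-nt guide, DNA-binding region only, 5'→3'.

    DNA-alphabet input (T) is converted to RNA (U) on construction.
    """

    name: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper().translate(_RNA_FROM_DNA)
        if len(seq) != GUIDE_LENGTH:
            raise ValueError(
                f"guide {self.name!r}: expected {GUIDE_LENGTH} nt, got {len(seq)}"
            )
        if not set(seq) <= set("ACGU"):
            raise ValueError(f"guide {self.name!r}: invalid letters in {seq!r}")
        object.__setattr__(self, "sequence", seq)

    @property
    def as_dna(self) -> str:
        return self.sequence.replace("U", "T")


@dataclass(frozen=True)
class TargetSite:
    """A 20-nt protospacer plus 3-nt PAM, optionally genome-located.

    The protospacer is written as the strand *complementary* to the one
    the guide base-pairs with, aligned so protospacer position i faces
    guide position i; the PAM is the 3 nt immediately 3' of the
    protospacer on the same strand.  Coordinates, when present, are
    0-based half-open on the plus-strand frame and cover the full 23-nt
    window.
    """

    protospacer: str
    pam: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self):
        proto = self.protospacer.upper()
        pam = self.pam.upper()
        if len(proto) != GUIDE_LENGTH:
            raise ValueError(f"protospacer must be {GUIDE_LENGTH} nt, got {len(proto)}")
        if not set(proto) <= set("ACGT"):
            raise ValueError(f"invalid protospacer letters in {proto!r}")
        if len(pam) != PAM_LENGTH or not set(pam) <= set("ACGT"):
            raise ValueError(f"PAM must be 3 nt over ACGT, got {pam!r}")
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam", pam)
        if self.start is not None and self.end is not None:
            if self.end - self.start != GUIDE_LENGTH + PAM_LENGTH:
                raise ValueError("site coordinates must span 23 nt")
        if self.strand is not None and self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def paired_strand(self) -> str:
        """The DNA strand the guide base-pairs with, 3'→5', aligned with the guide."""
        return self.protospacer.translate(_DNA_COMPLEMENT)

    def coordinate_key(self):
        return (
            self.chrom or "",
            self.start if self.start is not None else -1,
            self.strand or "+",
        )


@dataclass(frozen=True)
class PositionalContributions:
    """Free-energy contribution (kcal/mol) of each of the 19 stack positions."""

    values: Tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != N_STACKS:
            raise ValueError(f"expected {N_STACKS} positional values")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def total(self) -> float:
        return sum(self.values)


def pairing_states(g: GuideRNA, t: TargetSite) -> List[bool]:
    """True at position i (0-based here) iff guide and site match (U↔T)."""
    return [gb == pb for gb, pb in zip(g.as_dna, t.protospacer)]


def _mismatch_runs(match: Sequence[bool]) -> List[Tuple[int, int]]:
    """Maximal runs of mismatches as 0-based inclusive (start, stop)."""
    runs = []
    i = 0
    n = len(match)
    while i < n:
        if not match[i]:
            j = i
            while j + 1 < n and not match[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _stack_key(g: GuideRNA, t: TargetSite, i: int):
    """Hybrid stack key at 0-based stack index i (pairs i and i+1)."""
    paired = t.paired_strand
    return g.sequence[i : i + 2], paired[i : i + 2]


def positional_hybrid_contributions(
    g: GuideRNA,
    t: TargetSite,
    hybrid: EnergyTable,
    include_closing_in_division: bool = True,
) -> PositionalContributions:
    """Per-stack free-energy contributions of the guide–site hybrid.

    Match-run stacks take their Watson–Crick stack energy.  Each maximal
    mismatch run, with its closing stacks, is scored as one interior
    loop: the mismatch terms of the available closing stacks plus the
    loop initiation penalty for 2·(run length) unpaired nucleotides
    (symmetric loop — no bulges are modeled).  The loop total is divided
    equally over the stack positions the loop spans; by default the span
    includes the closing-stack positions, which for a single mismatch
    are the only positions touched.
    """
    if hybrid.kind is not DuplexKind.RNA_DNA:
        raise ValueError("positional contributions require the RNA:DNA table")
    match = pairing_states(g, t)
    values = [0.0] * N_STACKS

    for i in range(N_STACKS):
        if match[i] and match[i + 1]:
            values[i] = hybrid.energy(_stack_key(g, t, i))

    for a, b in _mismatch_runs(match):
        run_len = b - a + 1
        loop_e = hybrid.loop_penalty(2 * run_len)
        closing = []
        if a > 0:
            closing.append(a - 1)  # closing stack on the PAM-distal side
        else:
            logger.debug("terminal mismatch run at the 5' end: one closing stack only")
        if b < GUIDE_LENGTH - 1:
            closing.append(b)
        else:
            logger.debug("terminal mismatch run at the 3' end: one closing stack only")
        for c in closing:
            loop_e += hybrid.energy(_stack_key(g, t, c))

        span_lo = a - 1 if a > 0 else a
        span_hi = b if b < GUIDE_LENGTH - 1 else b - 1
        span = [p for p in range(span_lo, span_hi + 1) if 0 <= p < N_STACKS]
        if not include_closing_in_division:
            inner = [p for p in range(a, b) if 0 <= p < N_STACKS]
            if inner:
                span = inner
        share = loop_e / len(span)
        for p in span:
            values[p] += share

    return PositionalContributions(tuple(values))


def delta_g_h(contrib: PositionalContributions, weights) -> float:
    """Cas9-weighted hybridization energy: Σ_i Γ[i] · ΔG_i over the 19 stacks."""
    w = getattr(weights, "values", weights)
    if len(w) != N_STACKS:
        raise ValueError(f"expected {N_STACKS} positional weights, got {len(w)}")
    return float(sum(wi * ci for wi, ci in zip(w, contrib.values)))


def delta_g_o(t: TargetSite, dna: EnergyTable) -> float:
    """DNA-opening penalty: perfect-duplex energy of the target site.

    Sum over the 19 Watson–Crick DNA:DNA stacks of the protospacer and
    its complement; always negative for a fully specified 20-mer.
    """
    if dna.kind is not DuplexKind.DNA_DNA:
        raise ValueError("DNA opening penalty requires the DNA:DNA table")
    proto = t.protospacer
    comp = proto.translate(_DNA_COMPLEMENT)
    return float(
        sum(
            dna.energy((proto[i : i + 2], comp[i : i + 2]))
            for i in range(N_STACKS)
        )
    )
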