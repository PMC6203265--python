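"""Deterministic synthetic inputs: toy genomes and association datasets.

Everything the test-suite and examples consume is generated here from a
seed, so no external downloads are ever needed.  Genomes are i.i.d.
background sequence with 23-nt protospacer+PAM sites planted at known
coordinates with an exact number of mismatches; association datasets
are built with a known dominant stack position so weight training has a
recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .duplex import GUIDE_LENGTH, PAM_LENGTH, GuideRNA, TargetSite, reverse_complement
from .tables import EnergyTable
from .weights import AssociationDataset

__all__ = [
    "PlantSpec",
    "FixtureManifest",
    "make_genome",
    "make_association_dataset",
    "random_guide",
    "mutate_protospacer",
]

_DNA = np.array(list("ACGT"))
WINDOW = GUIDE_LENGTH + PAM_LENGTH


@dataclass(frozen=True)
class PlantSpec:
    """One site to plant: guide, mismatch count, strand, concrete PAM."""

    guide: GuideRNA
    mismatches: int = 0
    strand: str = "+"
    pam: str = "AGG"

    def __post_init__(self):
        if not 0 <= self.mismatches <= GUIDE_LENGTH:
            raise ValueError("mismatch count out of range")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site (plus-strand frame coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    protospacer: str
    pam: str
    mismatches: int


@dataclass(frozen=True)
class FixtureManifest:
    seed: int
    length: int
    gc: float
    planted: Tuple[PlantedSite, ...]


def random_guide(seed: int, name: str = "guide", gc: float = 0.5) -> GuideRNA:
    """A random 20-nt guide with the given expected GC content."""
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_DNA, size=GUIDE_LENGTH, p=probs))
    return GuideRNA(name=name, sequence=seq)


def mutate_protospacer(
    rng: np.random.Generator,
    guide: GuideRNA,
    k: int,
    positions: Optional[Sequence[int]] = None,
) -> str:
    """The guide's DNA protospacer with exactly k substitutions (0-based positions)."""
    proto = list(guide.as_dna)
    if positions is None:
        positions = rng.choice(GUIDE_LENGTH, size=k, replace=False)
    elif len(positions) != k:
        raise ValueError("positions must match the mismatch count")
    for p in positions:
        alternatives = [b for b in "ACGT" if b != proto[p]]
        proto[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(proto)


def make_genome(
    seed: int,
    length: int,
    plants: Sequence[PlantSpec],
    chrom: str = "chrT",
    gc: float = 0.41,
):
    """An i.i.d. background sequence with the requested sites planted.

    Planted windows never overlap one another; regeneration from the
    same arguments is byte-identical.  Returns (Genome, FixtureManifest).
    """
    from .search import Genome  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_DNA, size=length, p=probs)

    needed = len(plants) * WINDOW
    if needed > length:
        raise ValueError(f"cannot fit {len(plants)} sites in {length} nt")

    taken: List[Tuple[int, int]] = []
    records = []
    for spec in plants:
        window_dna = (
            mutate_protospacer(rng, spec.guide, spec.mismatches) + spec.pam.upper()
        )
        placed = None
        for _ in range(1000):
            start = int(rng.integers(0, length - WINDOW + 1))
            if all(start + WINDOW <= a or start >= b for a, b in taken):
                placed = start
                break
        if placed is None:
            raise ValueError("could not place a site without overlap")
        taken.append((placed, placed + WINDOW))
        oriented = window_dna if spec.strand == "+" else reverse_complement(window_dna)
        seq[placed : placed + WINDOW] = list(oriented)
        records.append(
            PlantedSite(
                chrom=chrom,
                start=placed,
                end=placed + WINDOW,
                strand=spec.strand,
                protospacer=window_dna[:GUIDE_LENGTH],
                pam=window_dna[GUIDE_LENGTH:],
                mismatches=spec.mismatches,
            )
        )

    genome = Genome({chrom: "".join(seq)})
    manifest = FixtureManifest(
        seed=seed, length=length, gc=gc, planted=tuple(records)
    )
    return genome, manifest


def make_association_dataset(
    seed: int,
    n: int,
    dominant_position: int = 19,
    hybrid: Optional[EnergyTable] = None,
    guide: Optional[GuideRNA] = None,
) -> AssociationDataset:
    """Association-rate records whose trained weights peak at one position.

    The guide carries its strongest (G/C-rich) stack at
    ``dominant_position`` (1-based stack index) and weak A/U context
    elsewhere; mismatches are planted anywhere except the two bases of
    the dominant stack, so the rate-weighted energy magnitude at that
    stack dominates and ``train_weights`` recovers it as the argmax.
    """
    if n < 19:
        raise ValueError("need at least 19 records")
    if not 1 <= dominant_position <= 19:
        raise ValueError("dominant_position must be in [1, 19]")
    rng = np.random.default_rng(seed)

    if guide is None:
        base = ["A"] * GUIDE_LENGTH
        base[dominant_position - 1] = "G"
        base[dominant_position] = "C"
        guide = GuideRNA(name="train-guide", sequence="".join(base))

    protected = {dominant_position - 1, dominant_position}
    free = [i for i in range(GUIDE_LENGTH) if i not in protected]
    records = []
    for _ in range(n):
        k = int(rng.integers(0, 4))
        positions = rng.choice(free, size=k, replace=False) if k else []
        proto = mutate_protospacer(rng, guide, k, positions=list(positions))
        rate = float(10 ** rng.uniform(-1.0, 2.0))
        site = TargetSite(protospacer=proto, pam="AGG")
        records.append((site, rate))
    return AssociationDataset(guide=guide, records=tuple(records))
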