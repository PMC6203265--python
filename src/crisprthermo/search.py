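"""Mismatch-tolerant, PAM-filtered protospacer search.

Finds every 23-nt window (20-nt protospacer + 3-nt PAM) on either
strand of a genome whose PAM matches an allowed pattern and whose
protospacer is within a Hamming-distance budget of the guide.  The
localization uses pigeonhole-partitioned exact seeding: the 20-mer is
split into max_mismatches+1 segments, so any hit with ≤ max_mismatches
substitutions contains at least one exact segment, and candidate
windows are enumerated from exact segment occurrences and then
verified.  Windows containing N are skipped (the energy tables are
undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from Bio import SeqIO

from .duplex import (
    GUIDE_LENGTH,
    PAM_LENGTH,
    GuideRNA,
    TargetSite,
    reverse_complement,
)
from .scoring import MissingOnTargetError, OffTargetSet, PamCorrection

__all__ = [
    "Genome",
    "SearchParams",
    "read_fasta",
    "find_sites",
    "annotate_on_target",
    "count_mismatches",
]

WINDOW = GUIDE_LENGTH + PAM_LENGTH


@dataclass(frozen=True)
class Genome:
    """Named uppercase DNA sequences (A/C/G/T/N), insertion-ordered."""

    sequences: Mapping[str, str]

    def __post_init__(self):
        cleaned = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            extra = set(seq) - set("ACGTN")
            if extra:
                raise ValueError(f"sequence {name!r} has invalid letters {sorted(extra)}")
            cleaned[name] = seq
        object.__setattr__(self, "sequences", cleaned)

    def __len__(self):
        return len(self.sequences)


@dataclass(frozen=True)
class SearchParams:
    """Search configuration: mismatch budget, PAM set, strandedness."""

    max_mismatches: int = 6
    allowed_pams: Tuple[str, ...] = ("NGG", "NAG", "NGA")
    both_strands: bool = True

    def __post_init__(self):
        if not 0 <= self.max_mismatches <= 19:
            raise ValueError("max_mismatches must be in [0, 19]")
        object.__setattr__(self, "allowed_pams", tuple(self.allowed_pams))

    def pam_ok(self, pam: str) -> bool:
        return any(
            all(p == "N" or p == b for p, b in zip(pat, pam))
            for pat in self.allowed_pams
        )


def read_fasta(path) -> Genome:
    """Parse a (multi-)FASTA file; soft-masked lowercase is uppercased."""
    path = Path(path)
    records = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"{path}: duplicate record name {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Genome(records)


def count_mismatches(guide_dna: str, protospacer: str) -> int:
    return sum(a != b for a, b in zip(guide_dna, protospacer))


def _segments(pattern: str, parts: int) -> List[Tuple[int, str]]:
    """Split pattern into `parts` near-equal segments with their offsets."""
    n = len(pattern)
    bounds = [round(k * n / parts) for k in range(parts + 1)]
    return [(bounds[k], pattern[bounds[k] : bounds[k + 1]]) for k in range(parts)]


def _candidate_starts(seq: str, pattern: str, k: int) -> Iterable[int]:
    """Pigeonhole seeding: window starts where `pattern` may occur with ≤ k mismatches."""
    candidates = set()
    for offset, segment in _segments(pattern, k + 1):
        if not segment:
            continue
        pos = seq.find(segment)
        while pos != -1:
            start = pos - offset
            if 0 <= start <= len(seq) - len(pattern):
                candidates.add(start)
            pos = seq.find(segment, pos + 1)
    return sorted(candidates)


def _scan_strand(
    name: str, seq: str, guide_dna: str, p: SearchParams, minus: bool
) -> List[TargetSite]:
    """All accepted windows on one strand, coordinates on the + frame."""
    hits = []
    n = len(seq)
    for start in _candidate_starts(seq, guide_dna, p.max_mismatches):
        if start + WINDOW > n:
            continue
        window = seq[start : start + WINDOW]
        if "N" in window:
            continue
        proto, pam = window[:GUIDE_LENGTH], window[GUIDE_LENGTH:]
        if not p.pam_ok(pam):
            continue
        if count_mismatches(guide_dna, proto) > p.max_mismatches:
            continue
        if minus:
            plus_start = n - (start + WINDOW)
            hits.append(
                TargetSite(
                    protospacer=proto,
                    pam=pam,
                    chrom=name,
                    start=plus_start,
                    end=plus_start + WINDOW,
                    strand="-",
                )
            )
        else:
            hits.append(
                TargetSite(
                    protospacer=proto,
                    pam=pam,
                    chrom=name,
                    start=start,
                    end=start + WINDOW,
                    strand="+",
                )
            )
    return hits


def find_sites(genome: Genome, g: GuideRNA, p: Optional[SearchParams] = None) -> List[TargetSite]:
    """Every candidate site of `g` in `genome` under the search parameters.

    Returned sites carry the protospacer/PAM as read on the strand they
    occur on (minus-strand hits report the reverse-complement window)
    with 0-based half-open plus-strand coordinates, sorted by
    (chrom, start, strand).
    """
    p = p or SearchParams()
    guide_dna = g.as_dna
    hits: List[TargetSite] = []
    for name, seq in genome.sequences.items():
        hits.extend(_scan_strand(name, seq, guide_dna, p, minus=False))
        if p.both_strands:
            hits.extend(
                _scan_strand(name, reverse_complement(seq), guide_dna, p, minus=True)
            )
    hits.sort(key=lambda t: (t.chrom, t.start, t.strand))
    return hits


def annotate_on_target(
    hits: List[TargetSite],
    guide: GuideRNA,
    declared_on: Optional[Tuple[str, int, str]] = None,
    pam: Optional[PamCorrection] = None,
) -> OffTargetSet:
    """Designate the on-target among search hits and build the target set.

    The on-target is the declared (chrom, start, strand) site if given,
    else the first perfect-match hit in coordinate order whose PAM the
    scorer recognizes.  Raises MissingOnTargetError when the guide has
    no perfect complementary target — such a set cannot be scored for
    specificity.
    """
    if not hits:
        raise MissingOnTargetError("no candidate sites found for the guide")
    pam = pam or PamCorrection()
    if declared_on is not None:
        for t in hits:
            if (t.chrom, t.start, t.strand) == declared_on:
                return OffTargetSet(guide=guide, on_target=t, sites=tuple(hits))
        raise MissingOnTargetError(
            f"declared on-target {declared_on} is not among the candidate sites"
        )
    guide_dna = guide.as_dna
    for t in sorted(hits, key=lambda t: t.coordinate_key()):
        if count_mismatches(guide_dna, t.protospacer) == 0 and pam.recognizes(t.pam):
            return OffTargetSet(guide=guide, on_target=t, sites=tuple(hits))
    raise MissingOnTargetError(
        "the guide has no perfect complementary target among the candidate sites"
    )
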