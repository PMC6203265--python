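"""Tabular readers/writers for target-site lists.

Two dialects are supported: the package's native TSV (lossless
round-trip of search hits and scores) and the Cas-OFFinder result
format, where the matched site is printed with mismatched letters in
lowercase.  BED6 export is provided for genome-browser work.  All
writers emit '#'-prefixed header lines carrying the package version
and scoring parameters, and are byte-stable for fixed inputs.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from . import __version__
from .duplex import GUIDE_LENGTH, PAM_LENGTH, GuideRNA, TargetSite
from .scoring import BindingEnergy, ScoringConfig
from .search import count_mismatches

__all__ = [
    "read_offtargets",
    "write_sites",
    "write_scores",
    "write_specificity",
    "write_bed",
    "write_weights",
    "read_weights",
    "MalformedRowError",
]

SITE_COLUMNS = [
    "guide_name", "chrom", "start", "end", "strand", "protospacer", "pam", "mismatches",
]
SCORE_COLUMNS = SITE_COLUMNS + ["dG_H", "dG_O", "dG_U", "delta_pam", "dG_B", "crispr_off"]
SPEC_COLUMNS = ["guide_name", "n_sites", "n_offtargets", "beta", "crispr_spec", "capped"]


class MalformedRowError(ValueError):
    """A row of an off-target file does not fit the declared dialect."""


def _header_lines(cfg: Optional[ScoringConfig], command: Optional[str]) -> List[str]:
    lines = [f"# crisprthermo {__version__}"]
    if cfg is not None:
        lines.append(
            f"# parameter_set={cfg.parameter_set} beta={cfg.beta:.6g} "
            f"folding_backend={cfg.folding_backend}"
        )
    if command:
        lines.append(f"# command: {command}")
    return lines


def _parse_native_row(row: Sequence[str], lineno: int) -> Tuple[str, TargetSite, int]:
    if len(row) != len(SITE_COLUMNS):
        raise MalformedRowError(
            f"row {lineno}: expected {len(SITE_COLUMNS)} columns, got {len(row)}"
        )
    name, chrom, start, end, strand, proto, pam, mm = row
    try:
        site = TargetSite(
            protospacer=proto,
            pam=pam,
            chrom=chrom or None,
            start=int(start) if start != "." else None,
            end=int(end) if end != "." else None,
            strand=strand if strand in "+-" else None,
        )
    except ValueError as exc:
        raise MalformedRowError(f"row {lineno}: {exc}") from exc
    return name, site, int(mm)


def _parse_cas_offinder_row(row: Sequence[str], lineno: int) -> Tuple[str, TargetSite, int]:
    if len(row) < 6:
        raise MalformedRowError(f"row {lineno}: Cas-OFFinder rows have 6 columns")
    pattern, chrom, pos, matched, strand, mm = row[:6]
    if len(matched) != GUIDE_LENGTH + PAM_LENGTH:
        raise MalformedRowError(
            f"row {lineno}: site sequence must be {GUIDE_LENGTH + PAM_LENGTH} nt, "
            f"got {len(matched)}"
        )
    lowercase = sum(1 for c in matched[:GUIDE_LENGTH] if c.islower())
    if lowercase != int(mm):
        raise MalformedRowError(
            f"row {lineno}: {lowercase} lowercase letters but mismatch column says {mm}"
        )
    try:
        start = int(pos)
        site = TargetSite(
            protospacer=matched[:GUIDE_LENGTH].upper(),
            pam=matched[GUIDE_LENGTH:].upper(),
            chrom=chrom,
            start=start,
            end=start + GUIDE_LENGTH + PAM_LENGTH,
            strand=strand,
        )
    except ValueError as exc:
        raise MalformedRowError(f"row {lineno}: {exc}") from exc
    return pattern, site, int(mm)


def read_offtargets(path, dialect: str = "native"):
    """Parse an off-target list; returns (guide_names, sites, mismatch_counts)."""
    parsers = {"native": _parse_native_row, "cas-offinder": _parse_cas_offinder_row}
    if dialect not in parsers:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(parsers)}")
    parse = parsers[dialect]
    names, sites, mismatches = [], [], []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if dialect == "native" and row == SITE_COLUMNS:
                continue
            name, site, mm = parse(row, lineno)
            names.append(name)
            sites.append(site)
            mismatches.append(mm)
    return names, sites, mismatches


def _site_row(guide: GuideRNA, site: TargetSite) -> List[str]:
    return [
        guide.name,
        site.chrom or "",
        str(site.start) if site.start is not None else ".",
        str(site.end) if site.end is not None else ".",
        site.strand or ".",
        site.protospacer,
        site.pam,
        str(count_mismatches(guide.as_dna, site.protospacer)),
    ]


def write_sites(path, guide: GuideRNA, sites: Iterable[TargetSite],
                cfg: Optional[ScoringConfig] = None, command: Optional[str] = None) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_lines(cfg, command):
            fh.write(line + "\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SITE_COLUMNS)
        for site in sites:
            w.writerow(_site_row(guide, site))


def write_scores(path, guide: GuideRNA,
                 scored: Iterable[Tuple[TargetSite, BindingEnergy]],
                 cfg: Optional[ScoringConfig] = None, command: Optional[str] = None) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_lines(cfg, command):
            fh.write(line + "\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SCORE_COLUMNS)
        for site, be in scored:
            w.writerow(
                _site_row(guide, site)
                + [
                    f"{be.dG_H:.4f}",
                    f"{be.dG_O:.4f}",
                    f"{be.dG_U:.4f}",
                    f"{be.delta_pam:.2f}",
                    f"{be.dG_B:.4f}",
                    f"{-be.dG_B:.4f}",
                ]
            )


def write_specificity(path, guide: GuideRNA, n_sites: int, score: float, capped: bool,
                      cfg: Optional[ScoringConfig] = None, command: Optional[str] = None) -> None:
    with open(path, "w", newline="") as fh:
        for line in _header_lines(cfg, command):
            fh.write(line + "\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SPEC_COLUMNS)
        w.writerow(
            [
                guide.name,
                str(n_sites),
                str(n_sites - 1),
                f"{(cfg.beta if cfg else 0):.6g}" if cfg else ".",
                f"{score:.4f}",
                "1" if capped else "0",
            ]
        )


def write_bed(path, guide: GuideRNA, sites: Iterable[TargetSite]) -> None:
    """BED6: name = guide name, score = mismatch count."""
    with open(path, "w", newline="") as fh:
        for site in sites:
            mm = count_mismatches(guide.as_dna, site.protospacer)
            fh.write(
                f"{site.chrom}\t{site.start}\t{site.end}\t{guide.name}\t{mm}\t{site.strand}\n"
            )


def write_weights(path, weights, command: Optional[str] = None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# crisprthermo {__version__}\n")
        if command:
            fh.write(f"# command: {command}\n")
        fh.write("position\tgamma\n")
        for i, v in enumerate(weights.values, start=1):
            fh.write(f"{i}\t{v:.6f}\n")


def read_weights(path):
    from .weights import PositionalWeights

    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            _, v = line.split("\t")
            values.append(float(v))
    return PositionalWeights(tuple(values))
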