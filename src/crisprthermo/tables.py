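"""Nearest-neighbor duplex free-energy tables.

Serves three duplex parameter sets — RNA:RNA, DNA:DNA and the RNA:DNA
hybrid — as :class:`EnergyTable` objects holding stack free energies
(ΔG°37, kcal/mol), mismatch-containing stack terms, and interior-loop
initiation penalties by loop size.

A stack is keyed by the top-strand dinucleotide read 5'→3' and the
bottom-strand dinucleotide read 3'→5' (antiparallel convention), so that
the i-th top letter pairs with the i-th bottom letter.  For the hybrid
table the top strand is the guide RNA and the bottom strand is the DNA
strand it base-pairs with.

The hybrid table ships with the experimentally measured Watson–Crick
subset; every other key over its alphabet is completed at load time as
the arithmetic mean of the corresponding RNA:RNA and DNA:DNA values
(U↔T substitution on the respective strand).  Only stacks containing at
least one Watson–Crick column are part of a table's alphabet: duplexes
are scored with mismatch runs as interior loops, which never require a
doubly-mismatched stack.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from types import MappingProxyType
from typing import Mapping, Tuple

__all__ = [
    "DuplexKind",
    "StackKey",
    "EnergyTable",
    "MissingParameterError",
    "load_tables",
    "stack_energy",
    "complete_hybrid_table",
]

StackKey = Tuple[str, str]

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

WC_RNA_RNA = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WC_DNA_DNA = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})
WC_RNA_DNA = frozenset({("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")})


class DuplexKind(str, Enum):
    """The three duplex chemistries the model distinguishes."""

    RNA_RNA = "RNA:RNA"
    DNA_DNA = "DNA:DNA"
    RNA_DNA = "RNA:DNA"

    @property
    def top_alphabet(self) -> frozenset:
        return DNA_ALPHABET if self is DuplexKind.DNA_DNA else RNA_ALPHABET

    @property
    def bottom_alphabet(self) -> frozenset:
        return RNA_ALPHABET if self is DuplexKind.RNA_RNA else DNA_ALPHABET

    @property
    def wc_pairs(self) -> frozenset:
        if self is DuplexKind.RNA_RNA:
            return WC_RNA_RNA
        if self is DuplexKind.DNA_DNA:
            return WC_DNA_DNA
        return WC_RNA_DNA


class MissingParameterError(KeyError):
    """A stack or loop parameter is absent from the requested table."""


def _is_wc_column(kind: DuplexKind, top: str, bottom: str) -> bool:
    return (top, bottom) in kind.wc_pairs


def _key_columns(key: StackKey):
    top, bottom = key
    return (top[0], bottom[0]), (top[1], bottom[1])


@dataclass(frozen=True)
class EnergyTable:
    """Immutable nearest-neighbor parameter set for one duplex kind."""

    kind: DuplexKind
    stacks: Mapping[StackKey, float]
    mismatch_terms: Mapping[StackKey, float]
    loop_init: Mapping[int, float]
    source: str = "default"

    def __post_init__(self):
        object.__setattr__(self, "stacks", MappingProxyType(dict(self.stacks)))
        object.__setattr__(
            self, "mismatch_terms", MappingProxyType(dict(self.mismatch_terms))
        )
        object.__setattr__(self, "loop_init", MappingProxyType(dict(self.loop_init)))

    def validate_key(self, key: StackKey) -> None:
        top, bottom = key
        if len(top) != 2 or len(bottom) != 2:
            raise ValueError(f"stack key must be two dinucleotides, got {key!r}")
        if not set(top) <= self.kind.top_alphabet:
            raise ValueError(
                f"top dinucleotide {top!r} not over {self.kind.value} top alphabet"
            )
        if not set(bottom) <= self.kind.bottom_alphabet:
            raise ValueError(
                f"bottom dinucleotide {bottom!r} not over {self.kind.value} bottom alphabet"
            )

    def energy(self, key: StackKey) -> float:
        """ΔG°37 of a stack, whether Watson–Crick or mismatch-containing."""
        self.validate_key(key)
        if key in self.stacks:
            return self.stacks[key]
        if key in self.mismatch_terms:
            return self.mismatch_terms[key]
        raise MissingParameterError(
            f"no {self.kind.value} parameter for stack {key[0]}/{key[1]}"
        )

    def loop_penalty(self, size: int) -> float:
        """Interior-loop initiation penalty for `size` unpaired nucleotides."""
        if size < 2:
            raise ValueError("interior loop size must be >= 2")
        if size in self.loop_init:
            return self.loop_init[size]
        largest = max(self.loop_init)
        if size > largest:
            # beyond the tabulated range: clamp to the largest tabulated size
            return self.loop_init[largest]
        raise MissingParameterError(
            f"no {self.kind.value} loop initiation for size {size}"
        )

    def alphabet_keys(self):
        """Every stack key with at least one Watson–Crick column."""
        tops = sorted(self.kind.top_alphabet)
        bots = sorted(self.kind.bottom_alphabet)
        for x in tops:
            for y in tops:
                for w in bots:
                    for z in bots:
                        left = _is_wc_column(self.kind, x, w)
                        right = _is_wc_column(self.kind, y, z)
                        if left or right:
                            yield (x + y, w + z)


def _read_packaged_tsv(name: str):
    ref = resources.files("crisprthermo.data").joinpath(name)
    with ref.open("r") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    header, body = rows[0], rows[1:]
    return header, body


_PARAM_SETS = {"default": ("nn_stacks.tsv", "loop_init.tsv")}


def _load_raw(source_id: str):
    if source_id not in _PARAM_SETS:
        raise ValueError(
            f"unknown parameter set {source_id!r}; available: {sorted(_PARAM_SETS)}"
        )
    stacks_file, loops_file = _PARAM_SETS[source_id]
    _, stack_rows = _read_packaged_tsv(stacks_file)
    _, loop_rows = _read_packaged_tsv(loops_file)

    stacks = {k: {} for k in DuplexKind}
    mismatches = {k: {} for k in DuplexKind}
    for kind_s, top, bottom, dg in stack_rows:
        kind = DuplexKind(kind_s)
        left, right = _key_columns((top, bottom))
        wc = _is_wc_column(kind, *left) and _is_wc_column(kind, *right)
        (stacks if wc else mismatches)[kind][(top, bottom)] = float(dg)

    loops = {k: {} for k in DuplexKind}
    for kind_s, size, dg in loop_rows:
        loops[DuplexKind(kind_s)][int(size)] = float(dg)
    return stacks, mismatches, loops


def load_tables(source_id: str = "default") -> Mapping[DuplexKind, EnergyTable]:
    """Load the packaged parameter set and complete the hybrid table.

    Returns a mapping from :class:`DuplexKind` to an immutable
    :class:`EnergyTable`.  The RNA:DNA table is returned already
    completed by averaging (see :func:`complete_hybrid_table`).
    """
    stacks, mismatches, loops = _load_raw(source_id)
    rna = EnergyTable(
        DuplexKind.RNA_RNA,
        stacks[DuplexKind.RNA_RNA],
        mismatches[DuplexKind.RNA_RNA],
        loops[DuplexKind.RNA_RNA],
        source=source_id,
    )
    dna = EnergyTable(
        DuplexKind.DNA_DNA,
        stacks[DuplexKind.DNA_DNA],
        mismatches[DuplexKind.DNA_DNA],
        loops[DuplexKind.DNA_DNA],
        source=source_id,
    )
    measured = EnergyTable(
        DuplexKind.RNA_DNA,
        stacks[DuplexKind.RNA_DNA],
        mismatches[DuplexKind.RNA_DNA],
        {},
        source=source_id,
    )
    hybrid = complete_hybrid_table(rna, dna, measured)
    return MappingProxyType(
        {DuplexKind.RNA_RNA: rna, DuplexKind.DNA_DNA: dna, DuplexKind.RNA_DNA: hybrid}
    )


def stack_energy(table: EnergyTable, key: StackKey) -> float:
    """Tabulated ΔG°37 for one stack; raises for absent/ill-typed keys."""
    return table.energy(key)


def _hybrid_to_rna_key(key: StackKey) -> StackKey:
    top, bottom = key
    return top, bottom.replace("T", "U")


def _hybrid_to_dna_key(key: StackKey) -> StackKey:
    top, bottom = key
    return top.replace("U", "T"), bottom


def complete_hybrid_table(
    rna: EnergyTable, dna: EnergyTable, measured: EnergyTable
) -> EnergyTable:
    """Fill the RNA:DNA table by averaging RNA:RNA and DNA:DNA parameters.

    Keys present in `measured` keep their measured value; every other key
    over the hybrid alphabet becomes ``(RNA:RNA + DNA:DNA) / 2`` under the
    U↔T strand correspondence.  Loop initiation penalties are likewise the
    per-size mean of the two homoduplex tables.
    """
    stacks: dict = {}
    mismatch_terms: dict = {}
    for key in measured.alphabet_keys():
        left, right = _key_columns(key)
        wc = _is_wc_column(DuplexKind.RNA_DNA, *left) and _is_wc_column(
            DuplexKind.RNA_DNA, *right
        )
        target = stacks if wc else mismatch_terms
        if key in measured.stacks:
            target[key] = measured.stacks[key]
        elif key in measured.mismatch_terms:
            target[key] = measured.mismatch_terms[key]
        else:
            try:
                r = rna.energy(_hybrid_to_rna_key(key))
                d = dna.energy(_hybrid_to_dna_key(key))
            except MissingParameterError as exc:
                raise MissingParameterError(
                    f"hybrid stack {key[0]}/{key[1]} missing from the measured set "
                    f"and not derivable by averaging: {exc}"
                ) from exc
            target[key] = (r + d) / 2.0

    sizes = set(rna.loop_init) & set(dna.loop_init)
    loop_init = {n: (rna.loop_init[n] + dna.loop_init[n]) / 2.0 for n in sorted(sizes)}
    if measured.loop_init:
        loop_init.update(measured.loop_init)
    return EnergyTable(
        DuplexKind.RNA_DNA, stacks, mismatch_terms, loop_init, source=measured.source
    )
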