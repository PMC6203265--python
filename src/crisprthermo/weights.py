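"""Cas9 positional influence weights Γ[1..19].

The protein clamps the guide–target heteroduplex unevenly along its
length, so the stability of each of the 19 base-pair stacks contributes
to binding with a position-specific weight.  The packaged weights were
trained on a massively parallel dCas9 association-rate dataset; the
training procedure itself is implemented here so the weights can be
re-derived from any dataset of (off-target sequence, association rate)
records for a single guide.

Training: for each stack position i, the per-position hybrid stack
energy of every off-target (raw stack terms, no interior-loop division)
is summed weighted by the record's association rate, giving W_i < 0.
Weights are then Γ[i] = log10(|W_i| / min_j |W_j|) + 1, so the least
influential position gets weight exactly 1.  The magnitude-ratio
reading of the normalization is what yields all-≥1 weights from
negative energy sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .duplex import GuideRNA, TargetSite, N_STACKS, _stack_key
from .tables import DuplexKind, EnergyTable, MissingParameterError

__all__ = [
    "PositionalWeights",
    "AssociationDataset",
    "packaged_weights",
    "train_weights",
    "per_position_stack_energies",
]

#: Production Γ_Cas9 weights, positions 1..19 (PAM-distal to PAM-proximal).
PACKAGED_GAMMA: Tuple[float, ...] = (
    1.80, 1.96, 1.90, 2.13, 1.38, 1.46, 1.00, 1.39, 1.51, 1.98,
    1.88, 1.72, 2.02, 1.93, 2.08, 1.94, 2.15, 2.04, 2.25,
)


@dataclass(frozen=True)
class PositionalWeights:
    """19 positional weights, all ≥ 1, minimum exactly 1 when trained."""

    values: Tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != N_STACKS:
            raise ValueError(f"expected {N_STACKS} weights, got {len(self.values)}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def __getitem__(self, i: int) -> float:
        return self.values[i]

    def __len__(self) -> int:
        return N_STACKS


@dataclass(frozen=True)
class AssociationDataset:
    """Association-rate records for one guide: (site, rate>0) pairs."""

    guide: GuideRNA
    records: Tuple[Tuple[TargetSite, float], ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("association dataset needs at least one record")
        for k, (site, rate) in enumerate(self.records):
            if rate <= 0:
                raise ValueError(
                    f"record {k}: association rates must be strictly positive, got {rate}"
                )
        object.__setattr__(self, "records", tuple(self.records))


def packaged_weights() -> PositionalWeights:
    """The shipped Γ_Cas9 weights (the production default)."""
    return PositionalWeights(PACKAGED_GAMMA)


def unit_weights() -> PositionalWeights:
    """All-ones weights: the unweighted nearest-neighbor model."""
    return PositionalWeights((1.0,) * N_STACKS)


def per_position_stack_energies(
    g: GuideRNA, t: TargetSite, hybrid: EnergyTable
) -> List[float]:
    """Raw hybrid stack energy at each of the 19 stacks, individually.

    Used during weight training: each stack is looked up on its own
    (Watson–Crick stack, or single-mismatch term); a stack whose two
    columns are both mismatched has no tabulated term and contributes 0.
    """
    out = []
    for i in range(N_STACKS):
        try:
            out.append(hybrid.energy(_stack_key(g, t, i)))
        except MissingParameterError:
            out.append(0.0)
    return out


def train_weights(data: AssociationDataset, hybrid: EnergyTable) -> PositionalWeights:
    """Derive Γ weights from association-rate data.

    W_i = Σ_n rate_n · (stack energy at position i for guide vs site_n);
    Γ[i] = log10(|W_i| / min_j |W_j|) + 1.  Errors if the W_i are of
    mixed sign or any is zero (the logarithm is then undefined).
    """
    if hybrid.kind is not DuplexKind.RNA_DNA:
        raise ValueError("training requires the RNA:DNA hybrid table")
    w = [0.0] * N_STACKS
    for site, rate in data.records:
        energies = per_position_stack_energies(data.guide, site, hybrid)
        for i in range(N_STACKS):
            w[i] += rate * energies[i]

    bad = [i + 1 for i, wi in enumerate(w) if wi >= 0]
    if bad and len(bad) < N_STACKS:
        raise ValueError(
            f"position-weighted energy sums of mixed sign; log-normalization "
            f"undefined at positions {bad}"
        )
    if any(wi == 0 for wi in w):
        zeros = [i + 1 for i, wi in enumerate(w) if wi == 0]
        raise ValueError(f"zero position-weighted energy sums at positions {zeros}")

    import math

    mags = [abs(wi) for wi in w]
    ref = min(mags)
    gamma = [math.log10(m / ref) + 1.0 for m in mags]
    return PositionalWeights(tuple(gamma))
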