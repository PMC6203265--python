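"""Binding free energy ΔG_B, per-site CRISPRoff score, and CRISPRspec.

ΔG_B[g,t] = δ_PAM · (ΔG_H[g,t] − ΔG_O[t] − ΔG_U[g]) combines the
Cas9-weighted hybridization energy, the penalty for melting the genomic
duplex, the penalty for unfolding the guide, and a multiplicative PAM
correction.  The CRISPRoff score of a site is −ΔG_B (higher = more
stable predicted binding).  CRISPRspec aggregates a guide's whole
target ensemble with a Boltzmann partition function: it is −log10 of
the summed probability mass of all off-targets,

    −log10( Σ_{t≠t_on} e^{−β·ΔG_B[g,t]} / Σ_{t} e^{−β·ΔG_B[g,t]} ),

evaluated in log-sum-exp form.  Higher CRISPRspec = more specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import List, Mapping, Optional, Sequence, Tuple

from .duplex import (
    GuideRNA,
    TargetSite,
    delta_g_h,
    delta_g_o,
    pairing_states,
    positional_hybrid_contributions,
)
from .folding import delta_g_u
from .tables import DuplexKind, EnergyTable, load_tables
from .weights import PositionalWeights, packaged_weights

__all__ = [
    "PamCorrection",
    "ScoringConfig",
    "BindingEnergy",
    "OffTargetSet",
    "UnrecognizedPamError",
    "MissingOnTargetError",
    "binding_energy",
    "crispr_off",
    "crispr_spec",
    "rank_offtargets",
    "DEFAULT_BETA",
    "SPECIFICITY_CAP",
]

#: 1/(R·T) at 37 °C with R = 1.987e-3 kcal/(mol·K): mol/kcal.
DEFAULT_BETA = 1.0 / (1.987e-3 * 310.15)
SPECIFICITY_CAP = 100.0


class UnrecognizedPamError(ValueError):
    """Site PAM matches none of the configured PAM patterns."""


class MissingOnTargetError(ValueError):
    """The target set contains no perfect-match on-target site."""


@dataclass(frozen=True)
class PamCorrection:
    """PAM → δ multiplier; first letter of each pattern is an N wildcard."""

    table: Mapping[str, float] = field(
        default_factory=lambda: {"NGG": 1.0, "NAG": 0.9, "NGA": 0.8}
    )

    def __post_init__(self):
        object.__setattr__(self, "table", MappingProxyType(dict(self.table)))
        for pat, delta in self.table.items():
            if len(pat) != 3 or not (0 < delta <= 1):
                raise ValueError(f"invalid PAM correction {pat!r}: {delta}")

    def delta(self, pam: str) -> float:
        for pat, value in self.table.items():
            if all(p == "N" or p == b for p, b in zip(pat, pam)):
                return value
        raise UnrecognizedPamError(f"PAM {pam!r} not recognized by {dict(self.table)}")

    def recognizes(self, pam: str) -> bool:
        try:
            self.delta(pam)
            return True
        except UnrecognizedPamError:
            return False


@dataclass(frozen=True)
class ScoringConfig:
    """Everything the scorer needs beyond the sequences themselves."""

    beta: float = DEFAULT_BETA
    pam: PamCorrection = field(default_factory=PamCorrection)
    weights: PositionalWeights = field(default_factory=packaged_weights)
    folding_backend: str = "auto"
    parameter_set: str = "default"
    specificity_cap: float = SPECIFICITY_CAP
    tables: Optional[Mapping[DuplexKind, EnergyTable]] = None

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.tables is None:
            object.__setattr__(self, "tables", load_tables(self.parameter_set))

    @property
    def hybrid(self) -> EnergyTable:
        return self.tables[DuplexKind.RNA_DNA]

    @property
    def dna(self) -> EnergyTable:
        return self.tables[DuplexKind.DNA_DNA]


@dataclass(frozen=True)
class BindingEnergy:
    """ΔG_B decomposition for one guide–site pair (kcal/mol)."""

    dG_H: float
    dG_O: float
    dG_U: float
    delta_pam: float
    dG_B: float


@dataclass(frozen=True)
class OffTargetSet:
    """A guide's candidate target ensemble, including the on-target."""

    guide: GuideRNA
    on_target: TargetSite
    sites: Tuple[TargetSite, ...]

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.on_target not in self.sites:
            raise MissingOnTargetError(
                "the designated on-target must be among the candidate sites"
            )

    @property
    def off_targets(self) -> List[TargetSite]:
        skipped = False
        out = []
        for s in self.sites:
            if not skipped and s == self.on_target:
                skipped = True
                continue
            out.append(s)
        return out


def binding_energy(g: GuideRNA, t: TargetSite, cfg: ScoringConfig) -> BindingEnergy:
    """Compose ΔG_H, ΔG_O, ΔG_U and δ_PAM into ΔG_B for one site."""
    delta = cfg.pam.delta(t.pam)  # raises UnrecognizedPamError for exotic PAMs
    contrib = positional_hybrid_contributions(g, t, cfg.hybrid)
    dg_h = delta_g_h(contrib, cfg.weights)
    dg_o = delta_g_o(t, cfg.dna)
    dg_u = delta_g_u(g, cfg.folding_backend).mfe
    dg_b = delta * (dg_h - dg_o - dg_u)
    return BindingEnergy(dG_H=dg_h, dG_O=dg_o, dG_U=dg_u, delta_pam=delta, dG_B=dg_b)


def crispr_off(g: GuideRNA, t_off: TargetSite, cfg: Optional[ScoringConfig] = None) -> float:
    """Per-site confidence score: −ΔG_B (higher = more stable binding)."""
    cfg = cfg or ScoringConfig()
    return -binding_energy(g, t_off, cfg).dG_B


def _log_sum_exp(terms: Sequence[float]) -> float:
    m = max(terms)
    return m + math.log(sum(math.exp(x - m) for x in terms))


def crispr_spec(
    target_set: OffTargetSet, cfg: Optional[ScoringConfig] = None
) -> Tuple[float, bool]:
    """Partition-function specificity of a guide over its target ensemble.

    Returns ``(score, capped)``: −log10 of the off-target fraction of
    the Boltzmann ensemble, computed with log-sum-exp; when the guide
    has no off-target at all the fraction is 0, the score is +∞, and
    the configured cap is reported with ``capped=True``.
    """
    cfg = cfg or ScoringConfig()
    offs = target_set.off_targets
    all_exponents = [
        -cfg.beta * binding_energy(target_set.guide, t, cfg).dG_B
        for t in target_set.sites
    ]
    if not offs:
        return cfg.specificity_cap, True
    on_index = target_set.sites.index(target_set.on_target)
    off_exponents = [x for k, x in enumerate(all_exponents) if k != on_index]
    log_num = _log_sum_exp(off_exponents)
    log_den = _log_sum_exp(all_exponents)
    score = -(log_num - log_den) / math.log(10.0)
    if score > cfg.specificity_cap:
        return cfg.specificity_cap, True
    return score, False


def rank_offtargets(
    target_set: OffTargetSet, cfg: Optional[ScoringConfig] = None
) -> List[Tuple[TargetSite, float]]:
    """Off-targets sorted by CRISPRoff score, best first.

    Ties break by genomic coordinate (chrom, start, strand); the
    on-target is excluded (score it separately with `crispr_off`).
    """
    cfg = cfg or ScoringConfig()
    scored = [
        (t, crispr_off(target_set.guide, t, cfg)) for t in target_set.off_targets
    ]
    scored.sort(key=lambda pair: (-pair[1],) + pair[0].coordinate_key())
    return scored
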