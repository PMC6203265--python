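"""ΔG_B assembly, CRISPRoff, and partition-function specificity."""

import math

import numpy as np
import pytest

from crisprthermo import (
    GuideRNA,
    OffTargetSet,
    PamCorrection,
    ScoringConfig,
    TargetSite,
    binding_energy,
    crispr_off,
    crispr_spec,
    rank_offtargets,
)
from crisprthermo.scoring import MissingOnTargetError, UnrecognizedPamError
from crisprthermo.synthetic import mutate_protospacer, random_guide
from crisprthermo.weights import unit_weights

from .oracles import dna_opening_energy, naive_specificity, whole_duplex_energy


def site_of(guide, pam="AGG", **kw):
    return TargetSite(protospacer=guide.as_dna, pam=pam, **kw)


def random_sites(rng, guide, n, with_coords=False, max_mm=6):
    sites = []
    for idx in range(n):
        proto = mutate_protospacer(rng, guide, int(rng.integers(1, max_mm + 1)))
        kw = {}
        if with_coords:
            kw = dict(chrom="chr1", start=idx * 100, end=idx * 100 + 23, strand="+")
        sites.append(TargetSite(protospacer=proto, pam="TGG", **kw))
    return sites


class TestBindingEnergy:
    def test_deterministic(self, cfg, unstructured_guide, perfect_site):
        a = binding_energy(unstructured_guide, perfect_site, cfg)
        b = binding_energy(unstructured_guide, perfect_site, cfg)
        assert a == b

    def test_composition_invariant(self, cfg, unstructured_guide, perfect_site):
        be = binding_energy(unstructured_guide, perfect_site, cfg)
        assert be.dG_B == pytest.approx(
            be.delta_pam * (be.dG_H - be.dG_O - be.dG_U)
        )

    def test_unweighted_toy_decomposition(self, tables, hybrid, dna):
        # unit weights and a structure-free guide reduce ΔG_B to
        # δ·(ΔG_H − ΔG_O), checkable by direct table sums
        cfg = ScoringConfig(weights=unit_weights())
        g = GuideRNA("toy", "A" * 20)
        t = site_of(g)
        be = binding_energy(g, t, cfg)
        assert be.dG_U == 0.0
        assert be.dG_H == pytest.approx(
            whole_duplex_energy(g.sequence, t.protospacer, hybrid)
        )
        assert be.dG_O == pytest.approx(dna_opening_energy(t.protospacer, dna))
        assert be.dG_B == pytest.approx(1.0 * (be.dG_H - be.dG_O))

    def test_unrecognized_pam_rejected(self, cfg, unstructured_guide):
        with pytest.raises(UnrecognizedPamError):
            binding_energy(unstructured_guide, site_of(unstructured_guide, "ATT"), cfg)


class TestCrisprOff:
    def test_is_negated_binding_energy(self, cfg):
        g = random_guide(21, "g")
        t = site_of(g)
        assert crispr_off(g, t, cfg) == pytest.approx(
            -binding_energy(g, t, cfg).dG_B
        )

    @pytest.mark.parametrize("pam,ratio", [("AAG", 0.9), ("AGA", 0.8)])
    def test_pam_correction_ratios_exact(self, cfg, pam, ratio):
        g = random_guide(33, "g")
        ngg = crispr_off(g, site_of(g, "AGG"), cfg)
        other = crispr_off(g, site_of(g, pam), cfg)
        assert other / ngg == pytest.approx(ratio, abs=1e-12)

    def test_on_target_outscores_every_single_mismatch_variant(self, cfg):
        g = random_guide(8, "g")
        s_on = crispr_off(g, site_of(g), cfg)
        for pos in range(20):
            for base in "ACGT":
                if base == g.as_dna[pos]:
                    continue
                proto = g.as_dna[:pos] + base + g.as_dna[pos + 1 :]
                s_mm = crispr_off(g, TargetSite(protospacer=proto, pam="AGG"), cfg)
                assert s_on >= s_mm


class TestCrisprSpec:
    def test_equal_energy_off_target_gives_log10_two(self, cfg, unstructured_guide):
        t_on = site_of(unstructured_guide, chrom="c", start=0, end=23, strand="+")
        t_off = site_of(unstructured_guide, chrom="c", start=100, end=123, strand="+")
        ots = OffTargetSet(
            guide=unstructured_guide, on_target=t_on, sites=(t_on, t_off)
        )
        score, capped = crispr_spec(ots, cfg)
        assert not capped
        assert score == pytest.approx(math.log10(2), abs=1e-12)

    def test_no_off_targets_reports_cap_with_flag(self, cfg, unstructured_guide):
        ots = OffTargetSet(
            guide=unstructured_guide,
            on_target=site_of(unstructured_guide),
            sites=(site_of(unstructured_guide),),
        )
        score, capped = crispr_spec(ots, cfg)
        assert capped and score == cfg.specificity_cap

    def test_agrees_with_naive_summation_on_fifty_sites(self, cfg):
        rng = np.random.default_rng(50)
        g = random_guide(51, "g")
        t_on = site_of(g)
        sites = [t_on] + random_sites(rng, g, 50)
        ots = OffTargetSet(guide=g, on_target=t_on, sites=tuple(sites))
        score, _ = crispr_spec(ots, cfg)
        dg_on = binding_energy(g, t_on, cfg).dG_B
        dg_off = [binding_energy(g, t, cfg).dG_B for t in sites[1:]]
        assert score == pytest.approx(
            naive_specificity(dg_on, dg_off, cfg.beta), abs=1e-9
        )

    def test_adding_an_off_target_strictly_decreases_specificity(self, cfg):
        # close-energy sites (1-2 mismatches) keep every Boltzmann weight
        # large enough for the decrease to register in double precision
        rng = np.random.default_rng(60)
        g = random_guide(61, "g")
        t_on = site_of(g)
        sites = [t_on, *random_sites(rng, g, 1, max_mm=2)]
        previous, _ = crispr_spec(
            OffTargetSet(guide=g, on_target=t_on, sites=tuple(sites)), cfg
        )
        for t in random_sites(rng, g, 8, max_mm=2):
            sites.append(t)
            score, _ = crispr_spec(
                OffTargetSet(guide=g, on_target=t_on, sites=tuple(sites)), cfg
            )
            assert score < previous
            previous = score

    def test_permutation_invariance(self, cfg):
        rng = np.random.default_rng(70)
        g = random_guide(71, "g")
        t_on = site_of(g)
        sites = [t_on] + random_sites(rng, g, 12)
        a, _ = crispr_spec(OffTargetSet(guide=g, on_target=t_on, sites=tuple(sites)), cfg)
        rng.shuffle(sites)
        b, _ = crispr_spec(OffTargetSet(guide=g, on_target=t_on, sites=tuple(sites)), cfg)
        assert a == pytest.approx(b, abs=1e-12)

    def test_beta_to_zero_limit_is_uniform_ensemble(self):
        cfg = ScoringConfig(beta=1e-8)
        rng = np.random.default_rng(80)
        g = random_guide(81, "g")
        t_on = site_of(g)
        sites = [t_on] + random_sites(rng, g, 9)
        score, _ = crispr_spec(
            OffTargetSet(guide=g, on_target=t_on, sites=tuple(sites)), cfg
        )
        assert score == pytest.approx(-math.log10(9 / 10), abs=1e-5)

    def test_on_target_required(self, unstructured_guide):
        other = TargetSite(protospacer="C" * 20, pam="AGG")
        with pytest.raises(MissingOnTargetError):
            OffTargetSet(
                guide=unstructured_guide,
                on_target=site_of(unstructured_guide),
                sites=(other,),
            )


class TestRanking:
    def test_singleton_and_order(self, cfg):
        rng = np.random.default_rng(90)
        g = random_guide(91, "g")
        t_on = site_of(g, chrom="c", start=0, end=23, strand="+")
        offs = random_sites(rng, g, 10, with_coords=True)
        ots = OffTargetSet(guide=g, on_target=t_on, sites=(t_on, *offs))
        ranked = rank_offtargets(ots, cfg)
        assert len(ranked) == 10
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        assert t_on not in [t for t, _ in ranked]

    def test_equal_scores_fall_back_to_coordinates(self, cfg, unstructured_guide):
        t_on = site_of(unstructured_guide, chrom="c", start=0, end=23, strand="+")
        # two copies of the same repeated site at different loci
        dup1 = TargetSite(
            protospacer="A" * 19 + "C", pam="TGG", chrom="c", start=500, end=523, strand="+"
        )
        dup2 = TargetSite(
            protospacer="A" * 19 + "C", pam="TGG", chrom="c", start=100, end=123, strand="+"
        )
        ots = OffTargetSet(
            guide=unstructured_guide, on_target=t_on, sites=(t_on, dup1, dup2)
        )
        ranked = rank_offtargets(ots, cfg)
        assert [t.start for t, _ in ranked] == [100, 500]


class TestPamCorrection:
    def test_defaults(self):
        pam = PamCorrection()
        assert pam.delta("AGG") == 1.0
        assert pam.delta("CAG") == 0.9
        assert pam.delta("TGA") == 0.8
        assert not pam.recognizes("ATT")

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            PamCorrection({"NGG": 1.5})

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError):
            ScoringConfig(beta=-1.0)
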