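"""Positional duplex energetics: ΔG_H decomposition and ΔG_O."""

import numpy as np
import pytest

from crisprthermo import (
    GuideRNA,
    TargetSite,
    delta_g_h,
    delta_g_o,
    pairing_states,
    positional_hybrid_contributions,
)
from crisprthermo.duplex import _stack_key
from crisprthermo.synthetic import mutate_protospacer, random_guide
from crisprthermo.weights import packaged_weights, unit_weights

from .oracles import dna_opening_energy, revcomp, whole_duplex_energy


def make_site(proto, pam="AGG"):
    return TargetSite(protospacer=proto, pam=pam)


class TestPairingStates:
    def test_identical_sequences_all_match(self, unstructured_guide, perfect_site):
        assert pairing_states(unstructured_guide, perfect_site) == [True] * 20

    def test_single_substitution_single_mismatch(self):
        g = GuideRNA("g", "GACGCAUAAAGAUGAGACGC")
        proto = list(g.as_dna)
        proto[4] = "A"
        states = pairing_states(g, make_site("".join(proto)))
        assert states.count(False) == 1 and states[4] is False

    def test_all_substituted_all_mismatch(self):
        g = GuideRNA("g", "A" * 20)
        assert pairing_states(g, make_site("C" * 20)) == [False] * 20

    def test_u_t_equivalence(self):
        g = GuideRNA("g", "U" * 20)
        assert pairing_states(g, make_site("T" * 20)) == [True] * 20


class TestPositionalContributions:
    def test_perfect_match_is_per_stack_energies(self, hybrid):
        g = GuideRNA("g", "GACGCAUAAAGAUGAGACGC")
        t = make_site(g.as_dna)
        contrib = positional_hybrid_contributions(g, t, hybrid)
        for i in range(19):
            assert contrib.values[i] == pytest.approx(
                hybrid.energy(_stack_key(g, t, i))
            )

    def test_single_interior_mismatch_divides_loop_equally(self, hybrid):
        # mismatch at position 10 (1-based): 1x1 loop over stacks 9 and 10
        g = GuideRNA("g", "GACGCAUAAAGAUGAGACGC")
        proto = list(g.as_dna)
        proto[9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[9]]
        t = make_site("".join(proto))
        contrib = positional_hybrid_contributions(g, t, hybrid)
        loop_total = (
            hybrid.energy(_stack_key(g, t, 8))
            + hybrid.energy(_stack_key(g, t, 9))
            + hybrid.loop_penalty(2)
        )
        assert contrib.values[8] == pytest.approx(loop_total / 2)
        assert contrib.values[9] == pytest.approx(loop_total / 2)
        # positions away from the loop keep their stack energies
        assert contrib.values[0] == pytest.approx(hybrid.energy(_stack_key(g, t, 0)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conservation_against_whole_duplex_oracle(self, hybrid, seed):
        """Sum of the 19 positional shares equals the loop-aware duplex total."""
        rng = np.random.default_rng(seed)
        for _ in range(340):
            g = random_guide(int(rng.integers(2**31)), "g")
            k = int(rng.integers(0, 7))
            proto = mutate_protospacer(rng, g, k)
            t = make_site(proto)
            contrib = positional_hybrid_contributions(g, t, hybrid)
            expected = whole_duplex_energy(g.sequence, proto, hybrid)
            assert contrib.total == pytest.approx(expected, abs=1e-9)

    def test_terminal_mismatch_runs_use_single_closing_stack(self, hybrid):
        g = GuideRNA("g", "GACGCAUAAAGAUGAGACGC")
        proto = list(g.as_dna)
        proto[0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[proto[0]]
        t = make_site("".join(proto))
        contrib = positional_hybrid_contributions(g, t, hybrid)
        expected_loop = hybrid.energy(_stack_key(g, t, 0)) + hybrid.loop_penalty(2)
        assert contrib.values[0] == pytest.approx(expected_loop)

    def test_all_mismatch_duplex_spreads_loop_penalty(self, hybrid):
        g = GuideRNA("g", "A" * 20)
        t = make_site("C" * 20)
        contrib = positional_hybrid_contributions(g, t, hybrid)
        assert contrib.total == pytest.approx(hybrid.loop_penalty(40))
        assert len(set(round(v, 12) for v in contrib.values)) == 1


class TestDeltaGH:
    def test_identity_weights_recover_unweighted_sum(self, hybrid, identity_weights):
        g = GuideRNA("g", "GACGCAUAAAGAUGAGACGC")
        contrib = positional_hybrid_contributions(g, make_site(g.as_dna), hybrid)
        assert delta_g_h(contrib, identity_weights) == pytest.approx(contrib.total)

    def test_packaged_weights_perfect_match_hand_sum(self, hybrid):
        g = GuideRNA("g", "GACGCAUAAAGAUGAGACGC")
        t = make_site(g.as_dna)
        contrib = positional_hybrid_contributions(g, t, hybrid)
        gamma = packaged_weights()
        expected = sum(
            gamma.values[i] * hybrid.energy(_stack_key(g, t, i)) for i in range(19)
        )
        assert delta_g_h(contrib, gamma) == pytest.approx(expected)

    def test_zero_contributions_give_zero(self, identity_weights):
        from crisprthermo.duplex import PositionalContributions

        contrib = PositionalContributions((0.0,) * 19)
        assert delta_g_h(contrib, identity_weights) == 0.0

    def test_length_mismatch_rejected(self, hybrid):
        g = GuideRNA("g", "A" * 20)
        contrib = positional_hybrid_contributions(g, make_site(g.as_dna), hybrid)
        with pytest.raises(ValueError, match="19"):
            delta_g_h(contrib, (1.0,) * 18)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_interior_mismatches_destabilize(self, hybrid, identity_weights, seed):
        g = random_guide(seed, "g")
        on = positional_hybrid_contributions(g, make_site(g.as_dna), hybrid)
        e_on = delta_g_h(on, identity_weights)
        for pos in range(1, 19):
            for base in "ACGT":
                if base == g.as_dna[pos]:
                    continue
                proto = g.as_dna[:pos] + base + g.as_dna[pos + 1 :]
                mm = positional_hybrid_contributions(g, make_site(proto), hybrid)
                assert e_on < delta_g_h(mm, identity_weights)


class TestDeltaGO:
    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_direct_table_sum(self, dna, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            proto = "".join(rng.choice(list("ACGT"), 20))
            t = make_site(proto)
            assert delta_g_o(t, dna) == pytest.approx(
                dna_opening_energy(proto, dna), abs=1e-9
            )

    def test_reverse_complement_symmetry(self, dna):
        rng = np.random.default_rng(7)
        for _ in range(200):
            proto = "".join(rng.choice(list("ACGT"), 20))
            t1 = make_site(proto)
            t2 = make_site(revcomp(proto))
            assert delta_g_o(t1, dna) == pytest.approx(delta_g_o(t2, dna))

    def test_strictly_negative(self, dna):
        rng = np.random.default_rng(13)
        for _ in range(200):
            proto = "".join(rng.choice(list("ACGT"), 20))
            assert delta_g_o(make_site(proto), dna) < 0

    def test_gc_duplex_more_stable_than_at_duplex(self, dna):
        assert delta_g_o(make_site("G" * 20), dna) < delta_g_o(make_site("A" * 20), dna)


class TestDomainTypes:
    def test_guide_converts_t_to_u_and_checks_length(self):
        g = GuideRNA("g", "ACGT" * 5)
        assert g.sequence == "ACGU" * 5
        with pytest.raises(ValueError, match="20"):
            GuideRNA("short", "ACGU")

    def test_site_validates_alphabet_and_span(self):
        with pytest.raises(ValueError):
            TargetSite(protospacer="N" * 20, pam="AGG")
        with pytest.raises(ValueError, match="23"):
            TargetSite(protospacer="A" * 20, pam="AGG", chrom="c", start=0, end=22)
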