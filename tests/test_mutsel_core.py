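"""Codon space, fixation probabilities, and generator construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nemus as nm
from nemus import mutsel_core as mc

from oracles import pfix_oracle, pfix_reversible_oracle

SP = nm.CODON_SPACE


class TestCodonSpace:
    def test_sense_codons_and_stops(self):
        assert SP.n == 61
        assert len(SP.codons) == len(set(SP.codons))
        for stop in ("TAA", "TAG", "TGA"):
            assert stop not in SP.codons

    def test_every_amino_acid_encoded(self):
        assert sorted(set(SP.aa_index)) == list(range(20))

    def test_neighbor_relation_symmetric_and_bounded(self):
        assert np.array_equal(SP.neighbor_mask, SP.neighbor_mask.T)
        degree = SP.neighbor_mask.sum(axis=1)
        assert degree.max() <= 9
        assert degree.min() >= 1
        assert not SP.neighbor_mask.diagonal().any()

    def test_neighbor_annotation(self):
        i, j = SP.index["AAA"], SP.index["AAG"]
        assert SP.neighbor_mask[i, j]
        assert SP.target_base[i, j] == "ACGT".index("G")
        assert SP.transition_mask[i, j]  # A<->G purine transition
        k = SP.index["AAC"]
        assert not SP.transition_mask[i, k]  # A->C transversion
        assert not SP.neighbor_mask[SP.index["AAA"], SP.index["GGA"]]


class TestSelectionCoefficient:
    @pytest.mark.parametrize(
        "fa,fb,expected",
        [
            (1.0, 1.0, 0.0),
            (1.0, 1.00002, 2.0e-5),
            (1.00002, 1.0, 1.0 / 1.00002 - 1.0),
        ],
    )
    def test_values(self, fa, fb, expected):
        assert nm.selection_coefficient(fa, fb) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            nm.selection_coefficient(0.0, 1.0)
        with pytest.raises(ValueError):
            nm.selection_coefficient(1.0, -2.0)


class TestFixationProbability:
    def test_neutral_limit_exact(self):
        assert nm.fixation_probability(0.0, 10**5) == 1.0 / (2 * 10**5)
        assert nm.fixation_probability(1e-14, 10**5) == 1.0 / (2 * 10**5)
        assert nm.fixation_probability(0.0, 10**5, "reversible") == 1.0 / (2 * 10**5)

    def test_against_high_precision_oracle(self):
        # includes the documented spot value ~2.0372e-5 at s = 1e-5
        assert nm.fixation_probability(1e-5, 10**5) == pytest.approx(
            2.0372e-5, rel=1e-4
        )
        for s in np.linspace(-2e-5, 2e-5, 41):
            if abs(s) < 1e-12:
                continue
            got = nm.fixation_probability(float(s), 10**5)
            assert got == pytest.approx(pfix_oracle(float(s), 10**5), rel=1e-8)
            got_rev = nm.fixation_probability(float(s), 10**5, "reversible")
            assert got_rev == pytest.approx(
                pfix_reversible_oracle(float(s), 10**5), rel=1e-8
            )

    def test_forms_agree_at_weak_scaled_selection(self):
        # |4 N s| <= 2 -> the two fixation forms are numerically very close
        N = 10**5
        for s in np.linspace(-0.5e-5, 0.5e-5, 21):
            a = nm.fixation_probability(float(s), N, "non_reversible")
            b = nm.fixation_probability(float(s), N, "reversible")
            assert abs(a - b) / a < 1e-4

    def test_range_error_names_offender(self):
        with pytest.raises(ValueError, match="0.001"):
            nm.fixation_probability(1e-3, 10**5)

    def test_monotone_in_s_and_in_unit_interval(self):
        s = np.linspace(-2e-5, 2e-5, 101)
        p = nm.fixation_probability(s, 10**5)
        assert np.all(np.diff(p) > 0)
        assert np.all(p > 0) and np.all(p <= 1)


class TestFitnessProfile:
    def test_anchor_and_bounds(self):
        with pytest.raises(ValueError):
            nm.FitnessProfile((1.0,) * 19 + (1.00001,))  # anchor must be 1
        with pytest.raises(ValueError):
            nm.FitnessProfile((1.001,) + (1.0,) * 19)  # beyond bound
        p = nm.FitnessProfile.from_free(np.full(19, 1.00003))
        assert p.f[-1] == 1.0
        assert p.free.shape == (19,)


class TestGenerator:
    def test_neutral_collapse_to_hky(self):
        # with all fitnesses 1, q_ab = mu * theta_target * kappa^[ti]
        mp = nm.MutationParams(kappa=3.0, theta=(0.1, 0.2, 0.3, 0.4), mu=2e-6)
        Q = nm.build_generator(nm.MutSelModel(mutation=mp))
        theta = np.array(mp.theta)
        expect = np.where(
            SP.neighbor_mask,
            mp.mu * theta[SP.target_base] * np.where(SP.transition_mask, mp.kappa, 1.0),
            0.0,
        )
        np.fill_diagonal(expect, -expect.sum(axis=1))
        assert np.allclose(Q, expect, rtol=1e-12, atol=1e-20)

    def test_multi_nucleotide_rate_zero(self, small_profile):
        Q = nm.build_generator(nm.MutSelModel(fitness=small_profile))
        assert Q[SP.index["AAA"], SP.index["GGA"]] == 0.0

    def test_row_sums_vanish(self, small_profile):
        Q = nm.build_generator(nm.MutSelModel(fitness=small_profile))
        assert np.abs(Q.sum(axis=1)).max() < 1e-12 * np.abs(Q).max()

    def test_synonymous_pairs_neutral(self, small_profile):
        mp = nm.MutationParams()
        Q = nm.build_generator(nm.MutSelModel(mutation=mp, fitness=small_profile))
        i, j = SP.index["GGA"], SP.index["GGG"]  # both glycine
        assert Q[i, j] == pytest.approx(mp.mu * mp.theta[2] * mp.kappa, rel=1e-12)


class TestScaling:
    def test_neutral_scaled_rate_is_one(self):
        m = nm.MutSelModel()
        Q = nm.scaled_generator(m)
        pi = nm.stationary_distribution(Q)
        assert float(pi @ -np.diag(Q)) == pytest.approx(1.0, rel=1e-10)

    def test_mu_cancels(self, small_profile):
        m1 = nm.MutSelModel(
            mutation=nm.MutationParams(mu=1e-6), fitness=small_profile
        )
        m2 = nm.MutSelModel(
            mutation=nm.MutationParams(mu=7e-4), fitness=small_profile
        )
        assert np.allclose(nm.scaled_generator(m1), nm.scaled_generator(m2), rtol=1e-10)

    def test_selected_rate_below_neutral(self, small_profile):
        Q = nm.scaled_generator(nm.MutSelModel(fitness=small_profile))
        pi = nm.stationary_distribution(Q)
        rate = float(pi @ -np.diag(Q))
        # purifying selection cannot raise the equilibrium rate above ~1
        assert rate <= 1.0 + 1e-3


class TestStationary:
    def test_uniform_for_symmetric_neutral(self):
        Q = nm.scaled_generator(nm.MutSelModel())
        pi = nm.stationary_distribution(Q)
        assert np.allclose(pi, 1.0 / 61, atol=1e-12)

    def test_residual_small_generic(self, small_profile):
        Q = nm.scaled_generator(
            nm.MutSelModel(
                mutation=nm.MutationParams(kappa=2.5, theta=(0.3, 0.2, 0.2, 0.3)),
                fitness=small_profile,
            )
        )
        pi = nm.stationary_distribution(Q)
        assert np.abs(pi @ Q).max() < 1e-10
        assert pi.min() >= 0 and pi.sum() == pytest.approx(1.0)

    def test_detailed_balance_violated_only_by_nonreversible(self, small_profile):
        Qn = nm.scaled_generator(nm.MutSelModel(fitness=small_profile))
        Qr = nm.scaled_generator(
            nm.MutSelModel(fitness=small_profile, fixation_form="reversible")
        )
        assert nm.detailed_balance_residual(Qn) > 1e-13
        assert nm.detailed_balance_residual(Qr) < 1e-12


class TestTransitionProbabilities:
    def test_zero_time_identity(self, small_profile):
        Q = nm.scaled_generator(nm.MutSelModel(fitness=small_profile))
        assert np.array_equal(nm.transition_probabilities(Q, 0.0), np.eye(61))

    def test_negative_time_rejected(self):
        Q = nm.scaled_generator(nm.MutSelModel())
        with pytest.raises(ValueError):
            nm.transition_probabilities(Q, -0.1)

    def test_rows_stochastic_and_nonnegative(self, small_profile):
        Q = nm.scaled_generator(nm.MutSelModel(fitness=small_profile))
        P = nm.transition_probabilities(Q, 0.7)
        assert np.abs(P.sum(axis=1) - 1.0).max() < 1e-10
        assert P.min() >= 0

    def test_semigroup(self, small_profile):
        Q = nm.scaled_generator(nm.MutSelModel(fitness=small_profile))
        P1 = nm.transition_probabilities(Q, 0.4)
        P2 = nm.transition_probabilities(Q, 1.1)
        P3 = nm.transition_probabilities(Q, 1.5)
        assert np.abs(P1 @ P2 - P3).max() < 1e-8

    def test_long_time_reaches_stationarity(self):
        # mild selection: strong profiles make the chain nearly reducible
        # (entry rates into unfit amino acids ~ e^(-4 N s)), so mixing within
        # any practical horizon requires modest population-scaled effects
        mild = nm.draw_fitness_profile(seed=2, half_width=2e-6)
        Q = nm.scaled_generator(nm.MutSelModel(fitness=mild))
        pi = nm.stationary_distribution(Q)
        P = nm.transition_probabilities(Q, 1e3)
        assert np.abs(P - pi[None, :]).max() < 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    kappa=st.floats(0.2, 10.0),
    a=st.floats(0.05, 1.0),
    c=st.floats(0.05, 1.0),
    g=st.floats(0.05, 1.0),
    t=st.floats(0.05, 1.0),
)
def test_neutral_collapse_property(kappa, a, c, g, t):
    """Neutral fitnesses collapse the model to pure HKY for any parameters."""
    tot = a + c + g + t
    mp = nm.MutationParams(kappa=kappa, theta=(a / tot, c / tot, g / tot, t / tot))
    Q = nm.build_generator(nm.MutSelModel(mutation=mp))
    theta = np.array(mp.theta)
    off = Q[SP.neighbor_mask]
    expect = (
        mp.mu
        * theta[SP.target_base[SP.neighbor_mask]]
        * np.where(SP.transition_mask[SP.neighbor_mask], kappa, 1.0)
    )
    assert np.allclose(off, expect, rtol=1e-12)
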