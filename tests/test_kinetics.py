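"""Hybridization-kinetics model: annealing law, mutual exclusion, steady
states, and agreement between the deterministic and stochastic solvers."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endosirna.kinetics import (
    KineticParams,
    KineticsError,
    annealing_rate,
    copresence_factor,
    gillespie,
    pervasive_params,
    steady_state,
)


class TestAnnealingRate:
    def test_zero_without_one_strand(self):
        assert annealing_rate(0, 10, 1.0, 0.01) == 0.0
        assert annealing_rate(10, 0, 1.0, 0.01) == 0.0

    def test_direct_arithmetic(self):
        assert annealing_rate(10, 10, 1.0, 0.01) == pytest.approx(1.0)

    @given(
        n_s=st.integers(0, 1000),
        n_a=st.integers(0, 1000),
        scale=st.integers(1, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_bilinearity(self, n_s, n_a, scale):
        """Doubling both strand counts quadruples the rate (the inverse-square
        concentration dependence written on counts)."""
        base = annealing_rate(n_s, n_a, 2.0, 0.05)
        assert annealing_rate(scale * n_s, scale * n_a, 2.0, 0.05) == pytest.approx(
            scale**2 * base
        )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(KineticsError):
            annealing_rate(1, 1, 0.0, 0.1)


class TestCopresenceFactor:
    def test_single_copy_exactly_zero(self):
        assert copresence_factor(1, 0.3, 0.3) == 0.0
        assert copresence_factor(1, 0.5, 0.5) == 0.0

    def test_no_sense_transcription_zero_for_all_m(self):
        for m in (1, 2, 5, 50):
            assert copresence_factor(m, 0.0, 0.4) == 0.0

    def test_two_copy_enumeration(self):
        """phi(2, .5, .5) by enumerating the 4 engagement states of 2 copies."""
        assert copresence_factor(2, 0.5, 0.5) == pytest.approx(0.5)
        # independent oracle: enumerate states of each copy in {S, A} (q=.5
        # each leaves no idle mass) and require both strands present
        states = list(itertools.product("SA", repeat=2))
        hit = sum(1 for s in states if "S" in s and "A" in s) / len(states)
        assert copresence_factor(2, 0.5, 0.5) == pytest.approx(hit)

    def test_enumeration_oracle_three_copies(self):
        """General phi matches brute-force enumeration over per-copy states."""
        q_s, q_a, m = 0.2, 0.3, 3
        probs = {"S": q_s, "A": q_a, "I": 1 - q_s - q_a}
        total = 0.0
        for combo in itertools.product("SAI", repeat=m):
            if "S" in combo and "A" in combo:
                total += math.prod(probs[c] for c in combo)
        assert copresence_factor(m, q_s, q_a) == pytest.approx(total)

    @given(m=st.integers(1, 40), q=st.floats(0.01, 0.45))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_copy_number(self, m, q):
        assert copresence_factor(m + 1, q, q) >= copresence_factor(m, q, q)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(KineticsError):
            copresence_factor(2, 0.7, 0.5)


def perturbative_R(p: KineticParams) -> float:
    """First-order (small k) closed form for steady-state siRNA, derived
    independently: linear ssRNA levels feed the two annealing channels."""
    m_c = p.copies_per_compartment
    n = p.n_compartments
    phi = p.phi()
    b_s, b_a = p.e_export + p.delta_s, p.e_export + p.delta_a
    S_L0, A_L0 = m_c * p.alpha_s / b_s, m_c * p.alpha_a / b_a
    S_C0 = n * p.e_export * S_L0 / p.delta_s
    A_C0 = n * p.e_export * A_L0 / p.delta_a
    flux = (
        n * phi * p.k_anneal * S_L0 * A_L0 / p.V_local
        + p.k_anneal * S_C0 * A_C0 / p.V_bulk
    )
    return flux * p.sirna_yield / p.delta_r


class TestSteadyState:
    def test_no_antisense_gives_linear_sense_levels(self):
        p = KineticParams(alpha_s=0.3, alpha_a=0.0, m=4)
        st_ = steady_state(p)
        assert st_.A_L == st_.A_C == st_.D == st_.R == 0.0
        b = p.e_export + p.delta_s
        assert st_.S_L == pytest.approx(4 * 0.3 / b)
        assert st_.S_C == pytest.approx(p.e_export * 4 * 0.3 / (b * p.delta_s))

    def test_no_annealing_gives_linear_both_strands(self):
        p = KineticParams(alpha_s=0.2, alpha_a=0.1, m=3, k_anneal=0.0)
        st_ = steady_state(p)
        assert st_.D == st_.R == 0.0
        b = p.e_export + p.delta_s
        assert st_.S_L == pytest.approx(3 * 0.2 / b)
        assert st_.A_L == pytest.approx(3 * 0.1 / b)

    @pytest.mark.parametrize("m,n_comp", [(1, 1), (3, 1), (3, 3), (10, 1), (10, 5)])
    def test_small_k_matches_perturbation_closed_form(self, m, n_comp):
        p = KineticParams(
            alpha_s=0.5, alpha_a=0.4, m=m, n_compartments=n_comp, k_anneal=1e-8
        )
        assert steady_state(p).R == pytest.approx(perturbative_R(p), rel=0.01)

    def test_fixed_point_satisfies_balance_equations(self):
        """The closed-form solution zeroes the ODE right-hand sides."""
        p = KineticParams(alpha_s=0.8, alpha_a=0.6, m=6, n_compartments=2)
        s = steady_state(p)
        n, m_c, phi = p.n_compartments, p.copies_per_compartment, p.phi()
        S_L, A_L = s.S_L / n, s.A_L / n  # per compartment
        u_loc = phi * p.k_anneal * S_L * A_L / p.V_local
        assert m_c * p.alpha_s - (p.e_export + p.delta_s) * S_L - u_loc == pytest.approx(
            0, abs=1e-10
        )
        u_blk = p.k_anneal * s.S_C * s.A_C / p.V_bulk
        assert n * p.e_export * S_L - p.delta_s * s.S_C - u_blk == pytest.approx(
            0, abs=1e-10
        )
        assert p.gamma_dicer * s.D == pytest.approx(n * u_loc + u_blk)
        assert p.delta_r * s.R == pytest.approx((n * u_loc + u_blk) * p.sirna_yield)

    def test_monotone_in_copy_number_at_fixed_total_output(self):
        """With m*alpha held constant and fixed per-copy engagement
        probabilities, clustered steady-state siRNA is non-decreasing in m
        (phi(m) non-decreasing while the local concentrations stay put)."""
        total_alpha = 0.6
        for k in (1e-4, 1e-3, 1e-2):
            prev = -1.0
            for m in (1, 2, 4, 8, 16):
                p = KineticParams(
                    alpha_s=total_alpha / m, alpha_a=total_alpha / m, m=m,
                    k_anneal=k, q_s=0.2, q_a=0.2,
                )
                r = steady_state(p).R
                assert r >= prev - 1e-12
                prev = r

    def test_single_copy_bulk_only_and_vanishing_with_volume(self):
        p1 = KineticParams(m=1)
        r_ref = steady_state(p1).R
        assert r_ref > 0  # bulk channel only
        grown = dataclasses.replace(p1, V_bulk=1e6)
        assert steady_state(grown).R < 1e-4 * r_ref

    def test_pervasive_preset_multi_vs_single(self):
        """At the ~1/14-molecules pervasive level, a 20-copy cluster makes
        siRNA while the matched single copy makes under 1% of it."""
        single = pervasive_params(1, "single")
        cluster = pervasive_params(20, "tandem")
        st1 = single
        assert steady_state(st1).ssRNA_total == pytest.approx(2 / 14, rel=0.05)
        r1, r20 = steady_state(single).R, steady_state(cluster).R
        assert r20 > 0
        assert r1 < 0.01 * r20

    def test_nonpositive_decay_rejected(self):
        with pytest.raises(KineticsError):
            steady_state(KineticParams(delta_r=0.0))


class TestGillespie:
    def test_no_transcription_stays_zero(self):
        p = KineticParams(alpha_s=0.0, alpha_a=0.0)
        tr = gillespie(p, 100.0, seed=1)
        assert np.all(tr.states == 0)

    def test_seed_determinism(self):
        p = KineticParams(alpha_s=0.3, alpha_a=0.3, m=3)
        t1 = gillespie(p, 300.0, seed=9)
        t2 = gillespie(p, 300.0, seed=9)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)

    def test_counts_never_negative_and_integer(self):
        p = KineticParams(alpha_s=0.5, alpha_a=0.5, m=4, n_compartments=2)
        tr = gillespie(p, 400.0, seed=3)
        assert tr.states.min() >= 0
        assert np.array_equal(tr.states, np.round(tr.states))

    def test_stoichiometry_of_every_event(self):
        """Each event changes species by one reaction's stoichiometry: the
        possible state deltas form a small known set."""
        p = KineticParams(alpha_s=0.4, alpha_a=0.4, m=2, duplex_length=460)
        y = p.sirna_yield
        tr = gillespie(p, 300.0, seed=11)
        deltas = {tuple(d) for d in np.diff(tr.states, axis=0).astype(int)}
        allowed = {
            (-1, -1, 0, 0, 1, 0),  # local annealing
            (1, 0, 0, 0, 0, 0), (0, 1, 0, 0, 0, 0),  # production
            (-1, 0, 1, 0, 0, 0), (0, -1, 0, 1, 0, 0),  # export
            (-1, 0, 0, 0, 0, 0), (0, -1, 0, 0, 0, 0),  # local decay
            (0, 0, -1, -1, 1, 0),  # bulk annealing
            (0, 0, -1, 0, 0, 0), (0, 0, 0, -1, 0, 0),  # bulk decay
            (0, 0, 0, 0, -1, y),  # dicing
            (0, 0, 0, 0, 0, -1),  # siRNA decay
            (0, 0, 0, 0, 0, 0),  # engagement switching
        }
        assert deltas <= allowed

    def test_ode_ssa_agreement_at_large_counts(self):
        """Time-averaged stochastic siRNA matches the deterministic steady
        state within 3 SE in the high-count, weak-annealing regime."""
        p = KineticParams(
            alpha_s=10.0, alpha_a=10.0, m=3, k_anneal=1e-6, duplex_length=1000
        )
        ode = steady_state(p)
        assert ode.S_C > 100
        means = [
            gillespie(p, 400.0, seed=s).time_average(burn_in=100.0).R
            for s in range(6)
        ]
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(np.mean(means) - ode.R) < 3 * se

    def test_clustered_beats_dispersed(self):
        """3 tandem copies vs 3 dispersed copies at equal total output:
        clustered makes more siRNA, in ODE strictly and in SSA at 3 SE."""
        cl = KineticParams(alpha_s=0.1, alpha_a=0.1, m=3, n_compartments=1,
                           duplex_length=1000)
        dp = dataclasses.replace(cl, n_compartments=3)
        assert steady_state(cl).R > steady_state(dp).R
        diffs = []
        for s in range(20):
            r_cl = gillespie(cl, 1500.0, seed=s).time_average(300.0).R
            r_dp = gillespie(dp, 1500.0, seed=10_000 + s).time_average(300.0).R
            diffs.append(r_cl - r_dp)
        se = np.std(diffs, ddof=1) / math.sqrt(len(diffs))
        assert np.mean(diffs) > 3 * se

    def test_invalid_horizon_rejected(self):
        with pytest.raises(KineticsError):
            gillespie(KineticParams(), 0.0, seed=1)
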