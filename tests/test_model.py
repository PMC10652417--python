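"""Unit tests for the core field definitions and right-hand sides."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import lognorm, norm

from cannstpp import (
    Kernel,
    ModelParams,
    NetworkState,
    RingGrid,
    StimulusSpec,
    connection_kernel,
    dynamics_rhs,
    external_input,
    field_derivatives,
    firing_rate,
    gating_activation,
    periodic_distance,
    priming_activation,
    total_input,
    wrap_angle,
)

SQRT_2PI = math.sqrt(2 * math.pi)

angles = st.floats(-50.0, 50.0, allow_nan=False)


class TestPeriodicDistance:
    @pytest.mark.parametrize(
        "x, xp, expected",
        [
            (1.3, 1.3, 0.0),
            (3.0, -3.0, 6.0 - 2 * math.pi),
            (-3.0, 3.0, -6.0 + 2 * math.pi),
            (0.1, 0.4, -0.3),
        ],
    )
    def test_values(self, x, xp, expected):
        assert periodic_distance(x, xp) == pytest.approx(expected, abs=1e-12)

    @given(angles, angles)
    def test_range_and_antisymmetry(self, x, xp):
        d = periodic_distance(x, xp)
        assert -math.pi < d <= math.pi + 1e-12
        back = periodic_distance(xp, x)
        # antisymmetric except at the +-pi boundary where both wrap to +pi
        if abs(d) < math.pi - 1e-9:
            assert back == pytest.approx(-d, abs=1e-9)

    def test_no_prewrap_needed(self):
        assert periodic_distance(7.0, 0.0) == pytest.approx(7.0 - 2 * math.pi)

    def test_broadcasts(self):
        x = np.array([0.0, 1.0, 2.0])
        d = periodic_distance(x, 0.5)
        assert d.shape == (3,)


class TestGrid:
    def test_spacing_and_range(self, grid):
        assert grid.dx == pytest.approx(2 * math.pi / grid.n_points)
        assert np.all(grid.x > -math.pi)
        assert grid.x[-1] == pytest.approx(math.pi)
        assert np.allclose(np.diff(grid.x), grid.dx)

    def test_mirror_is_involution(self, grid, rng):
        f = rng.normal(size=grid.n_points)
        assert np.array_equal(grid.mirror(grid.mirror(f)), f)

    def test_mirror_reflects_positions(self, grid):
        f = np.cos(grid.x - 0.7)
        expected = np.cos(-grid.x - 0.7)
        assert np.allclose(grid.mirror(f), expected, atol=1e-12)


class TestKernel:
    def test_peak_value(self, grid):
        J = connection_kernel(grid, 0.5)
        assert J[0, 0] == pytest.approx(2.0 / SQRT_2PI, rel=1e-12)

    def test_symmetric_positive_translation_invariant(self, grid):
        J = connection_kernel(grid, 0.5)
        assert np.allclose(J, J.T)
        assert np.all(J > 0)
        row_sums = J.sum(axis=1)
        assert np.allclose(row_sums, row_sums[0])

    def test_rejects_nonpositive_range(self, grid):
        with pytest.raises(ValueError, match="a"):
            Kernel(grid, 0.0)

    def test_fft_equals_dense(self, grid, rng):
        kern = Kernel(grid, 0.5)
        r = rng.normal(size=(4, grid.n_points))
        assert np.allclose(kern.apply(r), kern.apply_dense(r), atol=1e-12)


class TestFiringRate:
    def test_nonpositive_input_silences(self, grid):
        u = -np.abs(np.sin(grid.x)) - 0.1
        assert np.all(firing_rate(u, grid, 0.5, 0.5) == 0.0)

    def test_constant_field_closed_form(self, grid):
        u = np.ones(grid.n_points)
        expected = 1.0 / (1.0 + (0.5 / (8 * SQRT_2PI * 0.5)) * 2 * math.pi)
        r = firing_rate(u, grid, 0.5, 0.5)
        assert np.allclose(r, expected, rtol=1e-10)
        assert expected == pytest.approx(0.7614, abs=2e-4)

    def test_small_activity_limit(self, grid):
        c = 1e-6
        r = firing_rate(np.full(grid.n_points, c), grid, 0.5, 0.5)
        assert np.allclose(r, c * c, rtol=1e-6)

    def test_negative_nodes_still_inhibit(self, grid):
        # denominator uses u^2 of every node, numerator only positive ones
        u = np.where(grid.x > 0, 1.0, -1.0)
        r = firing_rate(u, grid, 0.5, 0.5)
        expected_denom = 1.0 + (0.5 / (8 * SQRT_2PI * 0.5)) * 2 * math.pi
        assert np.allclose(r[grid.x > 0], 1.0 / expected_denom, rtol=1e-10)
        assert np.all(r[grid.x <= 0] == 0.0)


class TestActivations:
    def test_gating_midpoint_and_tails(self):
        assert gating_activation(6.0, 6.0, 2.0) == pytest.approx(0.5)
        # Phi(-3) via the complementary error function (independent route)
        phi_m3 = 0.5 * math.erfc(3.0 / math.sqrt(2.0))
        assert gating_activation(0.0, 6.0, 2.0) == pytest.approx(phi_m3, rel=1e-9)
        assert phi_m3 == pytest.approx(0.00135, abs=2e-5)

    @given(st.floats(0, 30), st.floats(0, 30))
    def test_gating_monotone(self, ra, rb):
        lo, hi = sorted([ra, rb])
        assert gating_activation(lo, 6.0, 2.0) <= gating_activation(hi, 6.0, 2.0) + 1e-12

    def test_priming_zero_for_nonpositive_input(self):
        I = np.array([-2.0, -1e-8, 0.0])
        assert np.all(priming_activation(I, 0.25, 0.5) == 0.0)

    def test_priming_closed_form_values(self):
        at_mode = math.exp(0.25)
        expected = 1.0 / (at_mode * 0.5 * SQRT_2PI)
        assert priming_activation(at_mode, 0.25, 0.5) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(0.6214, abs=2e-4)
        at_one = (2.0 / SQRT_2PI) * math.exp(-0.125)
        assert priming_activation(1.0, 0.25, 0.5) == pytest.approx(at_one, rel=1e-10)
        assert at_one == pytest.approx(0.7041, abs=2e-4)

    def test_priming_matches_scipy_lognorm(self):
        I = np.linspace(0.05, 8.0, 40)
        expected = lognorm.pdf(I, s=0.5, scale=math.exp(0.25))
        assert np.allclose(priming_activation(I, 0.25, 0.5), expected, rtol=1e-10)

    def test_priming_single_interior_maximum(self):
        I = np.linspace(1e-3, 10.0, 2000)
        f = priming_activation(I, 0.25, 0.5)
        i_max = np.argmax(f)
        assert 0 < i_max < len(I) - 1
        diffs = np.sign(np.diff(f))
        assert np.all(diffs[:i_max] >= 0) and np.all(diffs[i_max:] <= 0)


class TestExternalInput:
    def test_peak_at_stimulus_position(self, grid):
        stim = StimulusSpec(A=3.0, z0_initial=grid.x[17], mode="static")
        I = external_input(grid, stim, 0.0)
        assert I[17] == pytest.approx(3.0)
        assert np.argmax(I) == 17

    def test_off_mode_is_zero(self, grid):
        stim = StimulusSpec(A=3.0, mode="off")
        assert np.all(external_input(grid, stim, 123.0) == 0.0)

    def test_moving_position(self):
        stim = StimulusSpec(A=1.0, z0_initial=0.0, v_ext=0.003, mode="moving")
        assert stim.position(1000.0) == pytest.approx(3.0)

    def test_abrupt_jump(self, grid):
        stim = StimulusSpec(A=1.0, z0_initial=0.0, mode="abrupt",
                            z0_after=1.0, t_jump=50.0)
        assert stim.position(49.9) == 0.0
        assert stim.position(50.0) == 1.0

    def test_validation(self):
        with pytest.raises(ValueError, match="mode"):
            StimulusSpec(mode="wobbly")
        with pytest.raises(ValueError, match="abrupt"):
            StimulusSpec(mode="abrupt")


class TestTotalInput:
    def test_zero_activity_passes_external_through(self, grid, kernel):
        r = np.zeros(grid.n_points)
        bump = np.exp(-grid.x**2)
        assert np.all(total_input(r, kernel, None) == 0.0)
        assert np.allclose(total_input(r, kernel, bump), bump)

    def test_uniform_rate_gives_row_sum(self, grid, kernel):
        c = 0.7
        r = np.full(grid.n_points, c)
        expected = c * kernel.matrix[0].sum() * grid.dx
        assert np.allclose(total_input(r, kernel, None), expected, rtol=1e-10)

    def test_shape_mismatch_rejected(self, grid, kernel):
        with pytest.raises(ValueError, match="length"):
            total_input(np.zeros(grid.n_points), kernel, np.zeros(7))


def _bump_state(grid, rng=None, seed=5):
    rng = rng or np.random.default_rng(seed)
    u = 8.0 * np.exp(-grid.x**2) + 0.3 * rng.normal(size=grid.n_points)
    S = np.abs(0.05 * np.exp(-grid.x**2 / 2))
    Q = 0.5 * np.exp(-grid.x**2 / 2)
    return NetworkState(u, S, Q, t=0.0)


class TestDynamicsRhs:
    def test_stpp_off_reduces_to_plain_cann(self, grid, kernel):
        params = ModelParams(alpha=0.0, beta=0.0)
        state = _bump_state(grid)
        state.S = np.zeros(grid.n_points)
        state.Q = np.zeros(grid.n_points)
        stim = StimulusSpec(A=2.0, mode="static")
        du, dS, dQ = dynamics_rhs(state, params, stim, grid, kernel)
        assert np.all(dS == 0.0)
        # Q is only charged through beta; with beta = 0 it stays empty
        assert np.all(dQ == 0.0)
        r = firing_rate(state.u, grid, params.k, params.a)
        I_tot = total_input(r, kernel, external_input(grid, stim, 0.0, params.a))
        assert np.allclose(du, (-state.u + I_tot) / params.tau_s)

    def test_full_q_blocks_priming_term(self, grid, kernel):
        params = ModelParams(alpha=0.0, beta=0.5)
        state = _bump_state(grid)
        state.Q = np.ones(grid.n_points)
        _, _, dQ = dynamics_rhs(
            state, params, StimulusSpec(A=3.0, mode="static"), grid, kernel
        )
        # with alpha = 0 and Q = 1 only the leak remains
        assert np.allclose(dQ, -1.0 / params.tau_2)

    def test_enhancement_rate_matches_closed_form(self, grid, kernel):
        params = ModelParams(alpha=0.02, beta=0.1)
        state = _bump_state(grid)
        state.S = np.zeros(grid.n_points)
        state.Q = np.full(grid.n_points, 0.5)
        r = firing_rate(state.u, grid, params.k, params.a)
        fs = norm.cdf((r - params.r0) / params.sigma_S)
        _, dS, _ = dynamics_rhs(
            state, params, StimulusSpec(mode="off"), grid, kernel
        )
        assert np.allclose(dS, 0.02 * 0.5 * fs, rtol=1e-9)
        # at a node firing exactly at r0, the rate is alpha * Q * 1/2
        i = np.argmin(np.abs(r - params.r0))
        assert dS[i] == pytest.approx(0.02 * 0.5 * fs[i])

    def test_translation_equivariance(self, grid, kernel, rng):
        params = ModelParams(alpha=0.05, beta=0.08)
        state = _bump_state(grid, rng)
        m = 37
        I_ext = 2.0 * np.exp(-grid.x**2)
        d0 = field_derivatives(state.u, state.S, state.Q, I_ext, params, grid, kernel)
        rolled = field_derivatives(
            np.roll(state.u, m), np.roll(state.S, m), np.roll(state.Q, m),
            np.roll(I_ext, m), params, grid, kernel,
        )
        for a, b in zip(d0, rolled):
            assert np.allclose(np.roll(a, m), b, atol=1e-13)

    def test_mirror_symmetry(self, grid, kernel, rng):
        params = ModelParams(alpha=0.05, beta=0.08)
        state = _bump_state(grid, rng)
        I_ext = 2.0 * np.exp(-(grid.x - 0.4) ** 2)
        d0 = field_derivatives(state.u, state.S, state.Q, I_ext, params, grid, kernel)
        dm = field_derivatives(
            grid.mirror(state.u), grid.mirror(state.S), grid.mirror(state.Q),
            grid.mirror(I_ext), params, grid, kernel,
        )
        for a, b in zip(d0, dm):
            assert np.allclose(grid.mirror(a), b, atol=1e-12)

    def test_nonfinite_state_raises(self, grid, kernel):
        state = _bump_state(grid)
        state.u[3] = np.inf
        with pytest.raises(FloatingPointError, match="t ="):
            dynamics_rhs(state, ModelParams(), StimulusSpec(mode="off"), grid, kernel)


class TestModelParams:
    def test_defaults_are_study_values(self):
        p = ModelParams()
        assert (p.tau_s, p.tau_1, p.tau_2) == (10.0, 50.0, 500.0)
        assert (p.a, p.k) == (0.5, 0.5)
        assert (p.r0, p.sigma_S, p.mu_Q, p.sigma_Q) == (6.0, 2.0, 0.25, 0.5)

    @pytest.mark.parametrize("bad", [
        {"tau_s": 0.0}, {"a": -0.5}, {"alpha": -1.0}, {"k": 0.0},
        {"sigma_Q": -2.0},
    ])
    def test_invalid_values_name_the_field(self, bad):
        (name, _), = bad.items()
        with pytest.raises(ValueError, match=name):
            ModelParams(**bad)

    def test_round_trip_and_unknown_key(self):
        p = ModelParams(alpha=0.02, beta=0.1)
        assert ModelParams.from_dict(p.to_dict()) == p
        with pytest.raises(ValueError, match="gamma"):
            ModelParams.from_dict({"gamma": 1.0})


def test_wrap_angle_range():
    vals = wrap_angle(np.linspace(-20, 20, 401))
    assert np.all(vals > -math.pi) and np.all(vals <= math.pi)
    assert wrap_angle(math.pi) == pytest.approx(math.pi)
    assert wrap_angle(-math.pi) == pytest.approx(math.pi)
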