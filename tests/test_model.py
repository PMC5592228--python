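"""Forward-physics unit and property tests: lineshapes, CWPE, steady state."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from spinbath.acquisition import AcquisitionError, MTAcquisition
from spinbath.model import (
    bloch_ode_oracle,
    gaussian_lineshape,
    mtr,
    omega1_cwpe,
    saturation_rates,
    steady_state_mf,
    steady_state_signal,
    super_lorentzian_lineshape,
)
from spinbath.tissue import TissueParameters

from conftest import random_valid_params


class TestAcquisitionValidation:
    def test_default_offsets_are_the_seven_kilohertz_set(self, acq):
        assert acq.offsets_hz == (1000.0, 2000.0, 4000.0, 8000.0, 10000.0, 12000.0, 16000.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"offsets_hz": (1000.0, 1000.0, 2000.0)},
            {"offsets_hz": (2000.0, 1000.0)},
            {"offsets_hz": (-1000.0, 2000.0)},
            {"tr_s": 0.01, "mt_pulse_duration_s": 0.012},
            {"mt_flip_deg": -5.0},
            {"lineshape": "lorentzian"},
            {"n_slices": 0},
        ],
    )
    def test_invalid_descriptors_rejected(self, kwargs):
        with pytest.raises(AcquisitionError):
            MTAcquisition(**kwargs)

    def test_json_round_trip_and_unknown_keys(self, tmp_path, acq):
        path = tmp_path / "acq.json"
        acq.to_json(path)
        assert MTAcquisition.from_json(path) == acq
        with pytest.raises(AcquisitionError, match="unknown"):
            MTAcquisition.from_dict({"offsets_hz": [1000.0, 2000.0], "bogus": 1})


class TestGaussianLineshape:
    def test_on_resonance_value(self):
        t2r = 10e-6
        assert gaussian_lineshape(0.0, t2r) == pytest.approx(t2r / math.sqrt(2 * math.pi))

    def test_unit_integral_over_angular_frequency(self):
        t2r = 10e-6
        val, _ = integrate.quad(
            lambda w: gaussian_lineshape(w / (2 * np.pi), t2r), -2e6, 2e6, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_monotone_decay_and_symmetry(self):
        t2r = 10e-6
        assert gaussian_lineshape(4000.0, t2r) < gaussian_lineshape(1000.0, t2r)
        assert gaussian_lineshape(-3000.0, t2r) == gaussian_lineshape(3000.0, t2r)

    def test_nonpositive_t2r_rejected(self):
        with pytest.raises(ValueError):
            gaussian_lineshape(1000.0, 0.0)


class TestSuperLorentzianLineshape:
    @staticmethod
    def _oracle(delta_hz, t2r):
        # independent fixed-order Gauss-Legendre quadrature of the kernel
        theta, w = np.polynomial.legendre.leggauss(4001)
        theta = 0.25 * math.pi * (theta + 1.0)
        w = w * 0.25 * math.pi
        u = 3.0 * np.cos(theta) ** 2 - 1.0
        omega = 2 * math.pi * abs(delta_hz)
        kern = np.where(
            np.abs(u) > 1e-300,
            np.sin(theta) / np.abs(u) * np.exp(-2.0 * (omega * t2r / u) ** 2),
            0.0,
        )
        return math.sqrt(2.0 / math.pi) * t2r * float(np.sum(w * kern))

    @pytest.mark.parametrize("delta", [1000.0, 2500.0, 8000.0, 16000.0])
    def test_agrees_with_quadrature_oracle(self, delta):
        got = super_lorentzian_lineshape(delta, 10e-6)
        assert got == pytest.approx(self._oracle(delta, 10e-6), rel=1e-8)

    def test_near_resonance_exceeds_gaussian_but_not_in_the_far_tail(self):
        # both kernels share the exp(-(w*T2r)^2/2) tail rate (theta -> 0
        # orientation), so the super-Lorentzian excess lives near resonance
        t2r = 10e-6
        for delta in (1000.0, 2000.0, 4000.0):
            assert super_lorentzian_lineshape(delta, t2r) > gaussian_lineshape(delta, t2r)
        assert super_lorentzian_lineshape(16000.0, t2r) < gaussian_lineshape(16000.0, t2r)

    def test_symmetric_in_offset_magnitude(self):
        assert super_lorentzian_lineshape(-5000.0, 10e-6) == pytest.approx(
            super_lorentzian_lineshape(5000.0, 10e-6), rel=1e-12
        )

    def test_domain_below_one_kilohertz_rejected(self):
        with pytest.raises(ValueError):
            super_lorentzian_lineshape(500.0, 10e-6)


class TestOmega1CWPE:
    def test_zero_flip_gives_zero(self, acq):
        assert omega1_cwpe(MTAcquisition(mt_flip_deg=0.0)) == 0.0

    def test_linear_in_flip_angle(self, acq):
        w1 = omega1_cwpe(acq)
        w2 = omega1_cwpe(MTAcquisition(mt_flip_deg=2 * acq.mt_flip_deg))
        assert w2 == pytest.approx(2 * w1, rel=1e-12)

    def test_matches_dense_trapezoid_oracle(self, acq):
        # rebuild the truncated-Gaussian envelope numerically and integrate
        tau = acq.mt_pulse_duration_s
        sigma = tau / 6.0
        t = np.linspace(0.0, tau, 2_000_001)
        env = np.exp(-((t - tau / 2.0) ** 2) / (2.0 * sigma**2))
        alpha = math.radians(acq.mt_flip_deg)
        w1_t = env * alpha / np.trapezoid(env, t)
        expected = math.sqrt(acq.n_slices * np.trapezoid(w1_t**2, t) / acq.tr_s)
        assert omega1_cwpe(acq) == pytest.approx(expected, rel=1e-9)

    def test_single_slice_reduces_power_by_sqrt_n(self, acq):
        one = omega1_cwpe(MTAcquisition(n_slices=1))
        assert omega1_cwpe(acq) == pytest.approx(math.sqrt(acq.n_slices) * one, rel=1e-12)

    def test_pulse_train_must_fit_inside_tr(self):
        with pytest.raises(AcquisitionError):
            MTAcquisition(mt_pulse_duration_s=0.025, n_slices=16)


class TestSteadyState:
    def test_no_saturation_limit_is_exactly_one(self, gm_params):
        assert steady_state_mf(gm_params, wr=0.0, wf=0.0) == pytest.approx(1.0, rel=1e-15)

    def test_uncoupled_pool_reduces_to_lorentzian_direct_saturation(self, acq):
        p = TissueParameters(f=0.0, kr=20.0, t2r=10e-6, t2f=60e-3, t1f=1.2)
        _, wf = saturation_rates(p, acq)
        got = steady_state_signal(p, acq).normalized
        np.testing.assert_allclose(got, p.r1f / (p.r1f + wf), rtol=1e-12)

    def test_normalized_signal_in_unit_interval_and_nondecreasing(self, acq, rng):
        for p in random_valid_params(rng, 25):
            z = steady_state_signal(p, acq).normalized
            assert np.all(z > 0) and np.all(z <= 1)
            assert np.all(np.diff(z) >= 0)

    def test_super_lorentzian_spectra_also_monotone(self, rng):
        acq_sl = MTAcquisition(lineshape="super_lorentzian")
        for p in random_valid_params(rng, 5):
            z = steady_state_signal(p, acq_sl).normalized
            assert np.all(np.diff(z) >= 0)

    def test_spin_density_scales_unnormalized_signal_linearly(self, acq, gm_params):
        s1 = steady_state_signal(gm_params, acq)
        s3 = steady_state_signal(gm_params.with_(sdf=3.0), acq)
        np.testing.assert_allclose(s3.values, 3.0 * s1.values, rtol=1e-14)
        np.testing.assert_allclose(s3.normalized, s1.normalized, rtol=1e-14)

    def test_closed_form_matches_ode_oracle_at_all_default_offsets(self, acq, gm_params):
        closed = steady_state_signal(gm_params, acq).normalized
        for k, delta in enumerate(acq.offsets_hz):
            ode = bloch_ode_oracle(gm_params, acq, delta)
            assert closed[k] == pytest.approx(ode, rel=1e-5)

    def test_ode_equilibrium_is_fixed_point_without_saturation(self, gm_params):
        quiet = MTAcquisition(mt_flip_deg=0.0)
        assert bloch_ode_oracle(gm_params, quiet, 8000.0) == pytest.approx(1.0, rel=1e-9)

    def test_ode_trajectory_monotone_between_steady_state_and_equilibrium(self, acq, gm_params):
        from scipy.integrate import solve_ivp

        wr, wf = saturation_rates(gm_params, acq, offsets_hz=[1000.0])
        wr, wf = float(wr[0]), float(wf[0])
        p = gm_params
        rhs = lambda t, y: [
            p.r1f * (1 - y[0]) - wf * y[0] - p.kf * y[0] + p.kr * y[1],
            p.r1r * (p.f - y[1]) - wr * y[1] - p.kr * y[1] + p.kf * y[0],
        ]
        sol = solve_ivp(rhs, (0, 30.0), [1.0, p.f], method="BDF",
                        rtol=1e-10, atol=1e-12, dense_output=True)
        traj = sol.sol(np.linspace(0, 30.0, 400))[0]
        ss = steady_state_mf(p, wr, wf)
        assert np.all(traj <= 1.0 + 1e-9)
        assert np.all(traj >= ss - 1e-6)


class TestMTR:
    @pytest.mark.parametrize("m0, m, expected", [(1.0, 1.0, 0.0), (1.0, 0.0, 100.0), (200.0, 150.0, 25.0)])
    def test_reference_values(self, m0, m, expected):
        assert mtr(m0, m) == expected

    def test_no_clipping_for_noisy_inputs(self):
        assert mtr(1.0, 1.1) == pytest.approx(-10.0)

    def test_nonpositive_m0_rejected(self):
        with pytest.raises(ValueError):
            mtr(0.0, 0.5)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    f=st.floats(0.01, 0.3),
    kr=st.floats(2.0, 80.0),
    t2r_us=st.floats(5.0, 20.0),
)
def test_closed_form_steady_state_always_physical(f, kr, t2r_us):
    """Normalized spectra stay in (0, 1] and rise with offset for any valid tissue."""
    acq = MTAcquisition()
    p = TissueParameters(f=f, kr=kr, t2r=t2r_us * 1e-6, t2f=60e-3, t1f=1.2)
    z = steady_state_signal(p, acq).normalized
    assert np.all(z > 0.0) and np.all(z <= 1.0)
    assert np.all(np.diff(z) >= -1e-12)
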