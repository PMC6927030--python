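"""Pump-layer tests: governing equation, steady states, sensitivity."""

import numpy as np
import pytest

from lvadctl.exceptions import NoOperatingPointError
from lvadctl.pump import (EPSILON_Q, PumpParams, PumpSignal, integrate_pump,
                          load_pump_params, pump_rhs, sensitivity_rhs,
                          speed_sensitivity, steady_state_flow)

# coefficient table as printed for the two pump generations
TABLE1 = {
    "S1": dict(a=-2.0400e1, b=7.1347e-6, c=-3.9880e0, d=-2.1035e-7, L=5.3037e0),
    "S2": dict(a=-1.0952e1, b=5.0372e-6, c=-2.6919e0, d=-2.0857e-7,
               e=9.3467e-10, f=4.8253e-12, L=3.6903e0),
}


@pytest.mark.parametrize("model_id", ["S1", "S2"])
def test_shipped_coefficients_exact(model_id):
    """The YAML-shipped coefficient sets equal the published table exactly."""
    p = load_pump_params(model_id)
    for name, value in TABLE1[model_id].items():
        assert getattr(p, name) == value
    if model_id == "S1":
        assert p.e == 0.0 and p.f == 0.0
    assert p.a < 0 and p.c < 0 and p.d < 0 and p.L > 0


def test_params_validation():
    with pytest.raises(ValueError):
        PumpParams(model_id="S1", a=-1, b=1e-6, c=-1, d=-1e-7, L=1.0, e=1e-9, f=0.0)
    with pytest.raises(ValueError):
        PumpParams(model_id="S2", a=-1, b=1e-6, c=-1, d=-1e-7, L=1.0)
    with pytest.raises(ValueError):
        PumpParams(model_id="S1", a=-1, b=1e-6, c=-1, d=-1e-7, L=-1.0)


class TestRHS:
    def test_equilibrium_at_rest(self, s1):
        assert pump_rhs(s1, 0.0, 0.0, 0.0) == 0.0

    def test_zero_flow_head(self, s1):
        """At H = −b·ω²/c the S1 equation balances at zero flow."""
        omega = 9000.0
        H0 = -s1.b * omega**2 / s1.c
        assert pump_rhs(s1, 0.0, omega, H0) == pytest.approx(0.0, abs=1e-9)

    def test_s2_steady_point(self, s2):
        """Q ≈ 5.18 L/min balances S2 at 9000 rpm / 100 mmHg."""
        q = steady_state_flow(s2, 9000.0, 100.0)
        assert q == pytest.approx(5.18, abs=0.01)
        assert pump_rhs(s2, q, 9000.0, 100.0) == pytest.approx(0.0, abs=1e-9)

    def test_s2_clamp_bounds_rhs(self, s2):
        """The Q⁻¹ term is evaluated at the clamped flow near zero."""
        q, w, H = 1e-9, 9000.0, 100.0
        got = pump_rhs(s2, q, w, H)
        expected = (s2.a * q + s2.b * w**2 + s2.c * H + s2.d * q * w**2
                    + s2.e * w**2 * H / EPSILON_Q + s2.f * w**2 * H**2) / s2.L
        assert np.isfinite(got)
        assert got == pytest.approx(expected, rel=1e-12)


class TestSteadyState:
    def test_s1_closed_form(self, s1):
        """Closed form −(bω²+cH)/(a+dω²) at the reference operating point."""
        q = steady_state_flow(s1, 9000.0, 100.0)
        expected = -(s1.b * 9000.0**2 + s1.c * 100.0) / (s1.a + s1.d * 9000.0**2)
        assert q == expected            # same arithmetic, to machine precision
        assert q == pytest.approx(4.784, abs=0.001)

    def test_s1_rest_is_zero(self, s1):
        assert steady_state_flow(s1, 0.0, 0.0) == 0.0

    def test_s2_no_root_out_of_range(self, s2):
        with pytest.raises(NoOperatingPointError):
            steady_state_flow(s2, 2000.0, 400.0)   # head far above zero-flow head

    def test_backflow_above_zero_flow_head(self, s1):
        """Static head beyond −b·ω²/c drives the S1 flow negative."""
        omega = 7000.0
        H0 = -s1.b * omega**2 / s1.c
        assert steady_state_flow(s1, omega, H0 * 1.2) < 0.0

    @pytest.mark.parametrize("omega", [5000.0, 7500.0, 10000.0])
    def test_monotonicity_in_operating_range(self, s1, omega):
        """Steady flow rises with speed and falls with head."""
        heads = np.arange(60.0, 141.0, 20.0)
        q = [steady_state_flow(s1, omega, h) for h in heads]
        assert all(a > b for a, b in zip(q, q[1:]))
        if omega < 10000.0:
            q_up = [steady_state_flow(s1, omega + 500.0, h) for h in heads]
            assert all(u > v for u, v in zip(q_up, q))


class TestIntegration:
    def test_fixed_point(self, s1):
        """Starting on the steady state, the solution stays there."""
        t = np.arange(0.0, 1.0, 1e-3)
        q0 = steady_state_flow(s1, 9000.0, 100.0)
        sig = integrate_pump(s1, t, np.full_like(t, 100.0),
                             np.full_like(t, 9000.0), Q0=q0)
        assert np.max(np.abs(sig.Q - q0)) < 1e-6

    def test_relaxation_time_constant(self, s1):
        """The linear S1 equation relaxes with τ = L/|a+dω²| ≈ 0.14 s."""
        tau = s1.L / abs(s1.a + s1.d * 9000.0**2)
        assert tau == pytest.approx(0.1417, abs=0.001)
        t = np.arange(0.0, 1.0, 1e-3)
        sig = integrate_pump(s1, t, np.full_like(t, 100.0),
                             np.full_like(t, 9000.0), Q0=0.5)
        q_inf = steady_state_flow(s1, 9000.0, 100.0)
        # after one time constant the gap has shrunk by ~e
        k = np.searchsorted(t, tau)
        gap0, gap_tau = q_inf - 0.5, q_inf - sig.Q[k]
        assert gap_tau / gap0 == pytest.approx(np.exp(-1.0), rel=0.02)

    @pytest.mark.parametrize("model", ["S1", "S2"])
    def test_oracle_equivalence_on_grid(self, model, s1, s2):
        """Constant-input integration converges onto the closed-form/rooted
        steady state over the whole (ω, H) operating grid."""
        pump = s1 if model == "S1" else s2
        t = np.arange(0.0, 2.5, 1e-3)
        for omega in np.arange(5000.0, 10001.0, 1000.0):
            for H in np.arange(40.0, 161.0, 40.0):
                try:
                    expected = steady_state_flow(pump, omega, H)
                except NoOperatingPointError:
                    # far above the zero-flow head the S2 residual has no
                    # forward root; those corners are outside the pump's
                    # operating region
                    assert model == "S2" and H > -pump.b * omega**2 / pump.c
                    continue
                sig = integrate_pump(pump, t, np.full_like(t, H),
                                     np.full_like(t, omega), Q0=expected * 0.7)
                assert sig.Q[-1] == pytest.approx(expected, abs=1e-4)

    def test_periodic_response_to_pulsatile_head(self, s1, pulsatile_head):
        """Under an 80 bpm head waveform the flow becomes cycle-periodic."""
        t, H = pulsatile_head
        sig = integrate_pump(s1, t, H, np.full_like(t, 9000.0), Q0=3.0)
        n = 750   # samples per cycle at 1 ms
        last, prev = sig.Q[-n:], sig.Q[-2 * n:-n]
        assert np.max(np.abs(last - prev)) < 1e-4


class TestSensitivity:
    @pytest.mark.parametrize("model", ["S1", "S2"])
    def test_matches_finite_difference_at_steady_state(self, model, s1, s2):
        """∂Q/∂ω from the sensitivity equation equals the central finite
        difference of the steady-state flow (δω = 1 rpm) after transients."""
        pump = s1 if model == "S1" else s2
        t = np.arange(0.0, 2.0, 1e-3)
        sig = integrate_pump(pump, t, np.full_like(t, 100.0),
                             np.full_like(t, 9000.0), Q0=1.0)
        fd = (steady_state_flow(pump, 9001.0, 100.0)
              - steady_state_flow(pump, 8999.0, 100.0)) / 2.0
        assert sig.dQdomega[-1] == pytest.approx(fd, abs=1e-3)

    def test_decays_without_speed(self, s1):
        """With ω = 0 every forcing term vanishes and s relaxes to zero."""
        t = np.arange(0.0, 3.0, 1e-3)
        sig = integrate_pump(s1, t, np.zeros_like(t), np.zeros_like(t),
                             Q0=0.0, s0=5e-3)
        assert abs(sig.dQdomega[-1]) < 1e-6

    @pytest.mark.parametrize("model", ["S1", "S2"])
    def test_pulsatile_agreement_with_two_point_reintegration(self, model, s1, s2,
                                                              pulsatile_head):
        """Sensitivity under a pulsatile head matches (Q(ω+δ) − Q(ω))/δ
        within 2 % relative amplitude after the transient."""
        pump = s1 if model == "S1" else s2
        t, H = pulsatile_head
        w = np.full_like(t, 8000.0)
        base = integrate_pump(pump, t, H, w, Q0=3.0)
        up = integrate_pump(pump, t, H, w + 5.0, Q0=3.0)
        fd = (up.Q - base.Q) / 5.0
        n = 750
        err = np.abs(base.dQdomega[-n:] - fd[-n:])
        assert err.max() < 0.02 * np.abs(fd[-n:]).max()

    def test_standalone_solver_matches_coupled(self, s1, pulsatile_head):
        """Re-solving the sensitivity along a stored signal reproduces the
        co-integrated series."""
        t, H = pulsatile_head
        sig = integrate_pump(s1, t, H, np.full_like(t, 9000.0), Q0=3.0)
        s = speed_sensitivity(s1, sig)
        assert np.max(np.abs(s - sig.dQdomega)) < 1e-5


class TestSignalIO:
    def test_csv_round_trip(self, s1, tmp_path):
        t = np.arange(0.0, 0.5, 1e-3)
        sig = integrate_pump(s1, t, np.full_like(t, 90.0),
                             np.full_like(t, 8000.0), Q0=2.0)
        path = tmp_path / "sig.csv"
        sig.to_csv(path)
        back = PumpSignal.from_csv(path)
        for col in ("t", "H", "omega", "Q", "dQdt", "dQdomega"):
            np.testing.assert_allclose(getattr(back, col), getattr(sig, col),
                                       rtol=0, atol=1e-12)

    def test_rejects_ragged_arrays(self):
        with pytest.raises(ValueError):
            PumpSignal(t=np.arange(3.0), H=np.zeros(3), omega=np.zeros(3),
                       Q=np.zeros(2), dQdt=np.zeros(3), dQdomega=np.zeros(3))

    def test_rejects_nonuniform_grid(self):
        t = np.array([0.0, 1e-3, 3e-3])
        with pytest.raises(ValueError):
            PumpSignal(t=t, H=np.zeros(3), omega=np.zeros(3), Q=np.zeros(3),
                       dQdt=np.zeros(3), dQdomega=np.zeros(3))
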