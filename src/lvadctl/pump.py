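"""Dynamic flow models of the Sputnik 1 and Sputnik 2 rotary blood pumps.

Both pumps obey a first-order governing equation for the flow ``Q``
through the pump given impeller speed ``omega`` and pressure head ``H``
(aortic minus ventricular pressure)::

    S1:  L dQ/dt = a·Q + b·ω² + c·H + d·Q·ω²
    S2:  L dQ/dt = a·Q + b·ω² + c·H + d·Q·ω² + e·Q⁻¹·ω²·H + f·ω²·H²

with empirically identified coefficients shipped in
``data/pump_coefficients.yaml``.  The unit system is fixed by the
coefficient magnitudes: ``Q`` in L/min, ``omega`` in rpm, ``H`` in mmHg,
``t`` in seconds.  Positive ``Q`` is forward flow (ventricle to aorta);
negative values represent backflow and are permitted.

The speed sensitivity ``s = ∂Q/∂ω`` needed by the valve-state detection
indices is produced by co-integrating the forward sensitivity equation
(the governing equation differentiated with respect to ``ω`` at fixed
``H``), which yields a smooth, grid-independent signal.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import IntegrationError, NoOperatingPointError

#: conversion factor between the pump unit (L/min) and the circulation unit (mL/s)
ML_S_PER_L_MIN = 1000.0 / 60.0

#: sign-preserving clamp applied to |Q| inside the S2 Q⁻¹ term, L/min.
#: The empirical S2 equation was never identified near zero flow; the clamp
#: bounds the right-hand side without affecting the operating range.
EPSILON_Q = 0.05

#: admissible flow range for steady-state root finding, L/min
Q_ROOT_RANGE = (EPSILON_Q, 15.0)

SIGNAL_COLUMNS = ("t", "H", "omega", "Q", "dQdt", "dQdomega")


@dataclass(frozen=True)
class PumpParams:
    """Coefficient set for one rotary blood pump.

    ``e`` and ``f`` are zero for the first-generation pump (S1) and
    strictly positive for the second generation (S2).
    """

    model_id: str
    a: float
    b: float
    c: float
    d: float
    L: float
    e: float = 0.0
    f: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in ("S1", "S2"):
            raise ValueError(f"unknown pump model {self.model_id!r}")
        if self.L <= 0:
            raise ValueError("fluid-inertia parameter L must be positive")
        if self.model_id == "S1" and (self.e != 0.0 or self.f != 0.0):
            raise ValueError("S1 must not carry the e/f head-coupling terms")
        if self.model_id == "S2" and (self.e == 0.0 or self.f == 0.0):
            raise ValueError("S2 requires all seven coefficients")

    @property
    def is_s2(self) -> bool:
        return self.model_id == "S2"


def _coefficient_table(path=None) -> dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = importlib.resources.files("lvadctl.data") / "pump_coefficients.yaml"
    return yaml.safe_load(ref.read_text())


def load_pump_params(model_id: str, path=None) -> PumpParams:
    """Load a shipped (or user-supplied YAML) coefficient set.

    Parameters
    ----------
    model_id : {"S1", "S2"} (case-insensitive)
    path : optional path to an alternative YAML coefficient file with the
        same schema as the shipped defaults.
    """
    table = _coefficient_table(path)
    key = model_id.lower()
    if key not in table:
        raise KeyError(f"no coefficient set for pump {model_id!r}")
    row = dict(table[key])
    return PumpParams(model_id=model_id.upper(), **row)


def _clamped(Q):
    """Sign-preserving clamp of |Q| at EPSILON_Q (for the S2 Q⁻¹ term)."""
    sign = np.where(np.asarray(Q) >= 0.0, 1.0, -1.0)
    return sign * np.maximum(np.abs(Q), EPSILON_Q)


def pump_rhs(params: PumpParams, Q, omega, H):
    """Right-hand side dQ/dt of the pump governing equation, L/min/s.

    Accepts scalars or broadcastable arrays.  For S2 the singular Q⁻¹
    term is evaluated at the clamped flow (see :data:`EPSILON_Q`).
    """
    w2 = omega * omega
    rhs = params.a * Q + params.b * w2 + params.c * H + params.d * Q * w2
    if params.is_s2:
        rhs = rhs + params.e * w2 * H / _clamped(Q) + params.f * w2 * H * H
    return rhs / params.L


def sensitivity_rhs(params: PumpParams, Q, s, omega, H):
    """Forward sensitivity equation ds/dt for s = ∂Q/∂ω at fixed H.

    Obtained by differentiating :func:`pump_rhs` with respect to omega;
    the derivative of the clamped Q⁻¹ term is zero inside the clamp.
    """
    w2 = omega * omega
    rhs = (
        params.a * s
        + 2.0 * params.b * omega
        + params.d * (s * w2 + 2.0 * Q * omega)
    )
    if params.is_s2:
        Qc = _clamped(Q)
        active = np.abs(Q) >= EPSILON_Q  # clamp freezes dependence on Q
        rhs = rhs + params.e * (
            -np.where(active, s / (Qc * Qc), 0.0) * w2 * H
            + 2.0 * omega * H / Qc
        )
        rhs = rhs + 2.0 * params.f * omega * H * H
    return rhs / params.L


def _steady_residual(params: PumpParams, Q, omega, H):
    return params.L * pump_rhs(params, Q, omega, H)


def steady_state_flow(params: PumpParams, omega: float, H: float) -> float:
    """Steady operating flow at constant speed and head, L/min.

    S1 admits the closed form ``Q = −(b·ω² + c·H)/(a + d·ω²)``.  For S2
    the residual is solved by bracketed root finding; the largest real
    root in ``(0, 15]`` L/min is returned (the physical branch — the
    second root of the quadratic-in-Q residual is negative or tiny and
    corresponds to the unstable balance of the singular term).
    """
    w2 = omega * omega
    if not params.is_s2:
        denom = params.a + params.d * w2
        if denom == 0.0:
            raise NoOperatingPointError("a + d·ω² vanishes; no steady state")
        return -(params.b * w2 + params.c * H) / denom
    if omega == 0.0 and H == 0.0:
        return 0.0
    # residual·Q is quadratic: (a+dω²)Q² + (bω²+cH+fω²H²)Q + eω²H = 0;
    # use its discriminant to bracket, then polish on the true residual.
    alpha = params.a + params.d * w2
    beta = params.b * w2 + params.c * H + params.f * w2 * H * H
    gamma = params.e * w2 * H
    disc = beta * beta - 4.0 * alpha * gamma
    if disc < 0.0:
        raise NoOperatingPointError("steady-state residual has no real root")
    roots = [(-beta + np.sqrt(disc)) / (2 * alpha), (-beta - np.sqrt(disc)) / (2 * alpha)]
    lo, hi = Q_ROOT_RANGE
    candidates = sorted(q for q in roots if lo <= q <= hi)
    if not candidates:
        raise NoOperatingPointError(
            f"no steady flow in [{lo}, {hi}] L/min at omega={omega}, H={H}"
        )
    q = candidates[-1]
    # polish against the exact residual (identical to the quadratic above
    # outside the clamp, so this is a no-op guard)
    f_lo, f_hi = (_steady_residual(params, x, omega, H) for x in (q - 1e-3, q + 1e-3))
    if f_lo * f_hi < 0:
        q = brentq(lambda x: _steady_residual(params, x, omega, H), q - 1e-3, q + 1e-3)
    return float(q)


@dataclass
class PumpSignal:
    """Time-aligned pump waveforms on one uniform grid.

    ``Q``, ``dQdt`` and ``dQdomega`` are outputs of integration, never
    inputs: ``dQdt`` is the governing equation evaluated along the
    solution (not a numerical difference) and ``dQdomega`` comes from
    the forward sensitivity equation.
    """

    t: np.ndarray
    H: np.ndarray
    omega: np.ndarray
    Q: np.ndarray
    dQdt: np.ndarray
    dQdomega: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, c), dtype=float) for c in SIGNAL_COLUMNS]
        n = arrays[0].shape[0]
        if any(a.shape != (n,) for a in arrays):
            raise ValueError("all signal arrays must share one length")
        dt = np.diff(arrays[0])
        if len(dt) and (dt.min() <= 0 or np.ptp(dt) > 1e-9 + 1e-6 * dt.mean()):
            raise ValueError("time grid must be uniform and increasing")
        for c, a in zip(SIGNAL_COLUMNS, arrays):
            setattr(self, c, a)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in SIGNAL_COLUMNS})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PumpSignal":
        df = pd.read_csv(path)
        return cls(**{c: df[c].to_numpy() for c in SIGNAL_COLUMNS})


def integrate_pump(
    params: PumpParams,
    t_grid: np.ndarray,
    H_series: np.ndarray,
    omega_series: np.ndarray,
    Q0: float = 0.0,
    s0: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> PumpSignal:
    """Integrate the pump flow and its speed sensitivity over a waveform.

    ``H_series`` and ``omega_series`` are sampled on ``t_grid`` and
    linearly interpolated inside the adaptive (stiff-capable) solver;
    the solution is returned on ``t_grid`` itself.
    """
    t = np.asarray(t_grid, dtype=float)
    H = np.asarray(H_series, dtype=float)
    w = np.asarray(omega_series, dtype=float)
    if not np.isfinite(Q0):
        raise ValueError("Q0 must be finite")

    def rhs(ti, y):
        h = np.interp(ti, t, H)
        om = np.interp(ti, t, w)
        return (
            pump_rhs(params, y[0], om, h),
            sensitivity_rhs(params, y[0], y[1], om, h),
        )

    sol = solve_ivp(
        rhs, (t[0], t[-1]), (Q0, s0), method="LSODA",
        t_eval=t, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"pump integration failed: {sol.message}")
    Q = sol.y[0]
    s = sol.y[1]
    dQdt = np.asarray(pump_rhs(params, Q, w, H), dtype=float)
    return PumpSignal(t=t, H=H, omega=w, Q=Q, dQdt=dQdt, dQdomega=s)


def speed_sensitivity(
    params: PumpParams,
    signal: PumpSignal,
    s0: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> np.ndarray:
    """Solve the (linear) sensitivity equation along an existing solution.

    Useful when ``Q`` was produced elsewhere (e.g. by the coupled
    circulation solver) and only ``∂Q/∂ω`` is needed.
    """
    t, H, w, Q = signal.t, signal.H, signal.omega, signal.Q

    def rhs(ti, y):
        h = np.interp(ti, t, H)
        om = np.interp(ti, t, w)
        q = np.interp(ti, t, Q)
        return (sensitivity_rhs(params, q, y[0], om, h),)

    sol = solve_ivp(rhs, (t[0], t[-1]), (s0,), method="LSODA",
                    t_eval=t, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"sensitivity integration failed: {sol.message}")
    return sol.y[0]
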