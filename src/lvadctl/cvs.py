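"""Lumped-parameter (0D) model of the circulation in a heart-failure state.

Eight compliant compartments are chained in a closed loop: left
ventricle -> aorta/systemic arteries -> systemic veins -> right atrium
-> right ventricle -> pulmonary arteries -> pulmonary veins -> left
atrium -> left ventricle.  The ventricles are time-varying-elastance
chambers with a double-Hill activation; the atria are passive compliant
compartments (no atrial kick).  The mitral, tricuspid and pulmonary
valves are ideal diodes with series resistance.  The aortic valve — the
valve whose state the detection indices must sense — carries a small
blood inertance in series, so that ejection ends with a physiological
flow deceleration and dicrotic notch; its opening (forward pressure
gradient) and closure (flow reversal) are resolved as exact integration
events.

The rotary blood pump is cannulated from the left ventricle to the
aorta: its flow state (L/min) is co-integrated with the compartment
volumes, driven by the pressure head ``H = P_ao − P_lv``, together with
the speed-sensitivity state used by the valve-state detection indices.

The shipped default parameter set is calibrated to a dilated
heart-failure baseline at 80 bpm (unsupported cardiac output
2.5–3.5 L/min, mean arterial pressure 60–80 mmHg, left-ventricular
end-diastolic pressure 15–25 mmHg), in which a 4 L/min pump flow target
is clinically meaningful.  Scenario studies scale left-ventricular
contractility (±15 %), heart rate (50–110 bpm) and systemic vascular
resistance (−25 % … +50 %) around this baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, VentricularCollapseError
from .pump import ML_S_PER_L_MIN, PumpParams, PumpSignal, pump_rhs, sensitivity_rhs

#: integrated aortic-valve flow (mL per beat) above which the valve
#: counts as open; operationalizes "near-zero aortic valve flow".
THRESHOLD_AV = 1.0

#: compartment order in the state vector (volumes, mL); the full state
#: is [volumes(8), q_av (mL/s), Q_pump (L/min), dQ/domega]
COMPARTMENTS = ("lv", "la", "rv", "ra", "ao", "sv", "pa", "pv")
N_STATES = 11
IDX_QAV, IDX_Q, IDX_S = 8, 9, 10


@dataclass(frozen=True)
class CVSParams:
    """Circulation parameters and scenario scaling factors.

    Units: elastances mmHg/mL, compliances mL/mmHg, resistances
    mmHg·s/mL, inertance mmHg·s²/mL, volumes mL, heart rate beats/min.
    ``contractility_scale`` multiplies the left-ventricular peak
    elastance only; ``svr_scale`` multiplies the systemic vascular
    resistance.
    """

    hr: float = 80.0
    # ventricular elastances (dilated heart-failure baseline)
    emax_lv: float = 0.36
    emin_lv: float = 0.08
    emax_rv: float = 0.42
    emin_rv: float = 0.035
    # exponential end-diastolic PV relation of the LV (dilated HF hearts
    # stiffen steeply with volume): P_ed = ed_a·(exp(ed_b·(V−V0)) − 1).
    # With ed_b = 0 the diastolic branch is linear with slope emin_lv.
    ed_a_lv: float = 0.0
    ed_b_lv: float = 0.0
    # passive compliances
    c_la: float = 13.0
    c_ra: float = 16.0
    c_ao: float = 0.5
    c_sv: float = 65.0
    c_pa: float = 4.2
    c_pv: float = 12.0
    # resistances
    r_mv: float = 0.006
    r_av: float = 0.008
    r_tv: float = 0.004
    r_pv: float = 0.0055
    r_sys: float = 1.15
    r_pul: float = 0.07
    r_vr: float = 0.032
    r_pvr: float = 0.014
    # aortic valve inertance
    l_av: float = 6.0e-4
    # unstressed volumes
    v0_lv: float = 20.0
    v0_la: float = 10.0
    v0_rv: float = 18.0
    v0_ra: float = 10.0
    v0_ao: float = 560.0
    v0_sv: float = 2650.0
    v0_pa: float = 120.0
    v0_pv: float = 360.0
    # initial (diastolic) filling pressures used to build the start state
    init_p_sv: float = 10.5
    init_p_pv: float = 14.0
    # systolic-duration coefficient: T_sys = sys_coeff * sqrt(60/HR)
    sys_coeff: float = 0.32
    # scenario scaling
    contractility_scale: float = 1.0
    svr_scale: float = 1.0
    # behaviour on negative compartment volume
    on_collapse: str = "warn"

    def __post_init__(self) -> None:
        if not (40.0 <= self.hr <= 140.0):
            raise ValueError("heart rate must lie in [40, 140] bpm")
        if not (0.85 - 1e-9 <= self.contractility_scale <= 1.15 + 1e-9):
            raise ValueError("contractility_scale must lie in [0.85, 1.15]")
        if not (0.75 - 1e-9 <= self.svr_scale <= 1.50 + 1e-9):
            raise ValueError("svr_scale must lie in [0.75, 1.50]")
        for name in ("c_la", "c_ra", "c_ao", "c_sv", "c_pa", "c_pv",
                     "r_mv", "r_av", "r_tv", "r_pv", "r_sys", "r_pul",
                     "r_vr", "r_pvr", "l_av", "emax_lv", "emin_lv",
                     "emax_rv", "emin_rv", "sys_coeff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.on_collapse not in ("warn", "raise"):
            raise ValueError("on_collapse must be 'warn' or 'raise'")

    @property
    def period(self) -> float:
        """Cardiac cycle length, s."""
        return 60.0 / self.hr

    @property
    def t_sys(self) -> float:
        """Systolic duration, s (shortens with heart rate)."""
        return self.sys_coeff * math.sqrt(self.period)

    def with_scenario(self, **kwargs) -> "CVSParams":
        return replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        """Write the parameter set as a YAML file."""
        import dataclasses
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CVSParams":
        """Load and validate a parameter set from YAML."""
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in __import__("dataclasses").fields(cls)}
        if unknown:
            raise ValueError(f"unknown circulation parameters: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# time-varying elastance

_M1, _M2 = 1.32, 27.4  # double-Hill exponents
_ACT_NORM_CACHE: dict[float, float] = {}


def _activation_raw(t, t_sys):
    tau1 = 0.60 * t_sys
    tau2 = 1.00 * t_sys
    g1 = (t / tau1) ** _M1
    g2 = (t / tau2) ** _M2
    return (g1 / (1.0 + g1)) / (1.0 + g2)


def activation(t_in_cycle, params: CVSParams):
    """Normalized ventricular activation e_n(t) in [0, 1] (double-Hill)."""
    t_sys = params.t_sys
    key = round(t_sys, 12)
    norm = _ACT_NORM_CACHE.get(key)
    if norm is None:
        tt = np.linspace(0.0, 2.0 * t_sys, 2001)
        norm = float(_activation_raw(tt, t_sys).max())
        _ACT_NORM_CACHE[key] = norm
    t = np.mod(t_in_cycle, params.period)
    return _activation_raw(t, t_sys) / norm


def elastance(t_in_cycle, params: CVSParams, chamber: str):
    """Instantaneous chamber elastance E(t), mmHg/mL.

    The contractility scaling applies to the left ventricle only.
    """
    e_n = activation(t_in_cycle, params)
    if chamber == "lv":
        emax = params.contractility_scale * params.emax_lv
        emin = params.emin_lv
    elif chamber == "rv":
        emax = params.emax_rv
        emin = params.emin_rv
    else:
        raise ValueError(f"unknown chamber {chamber!r}")
    return emin + (emax - emin) * e_n


# ---------------------------------------------------------------------------
# pressures and mass balances

def lv_pressure(t_in_cycle, v_lv, params: CVSParams):
    """Left-ventricular pressure: activation-blended ES/ED PV relations.

    ``P = e_n·E_es·(V−V0) + (1−e_n)·P_ed(V)`` with the end-systolic
    elastance scaled by contractility and an end-diastolic branch that
    is linear (slope ``emin_lv``) or exponential when ``ed_b_lv > 0``.
    With a linear branch this reduces exactly to the classical
    time-varying elastance E(t)·(V−V0).
    """
    act = activation(t_in_cycle, params)
    dv = v_lv - params.v0_lv
    p_es = params.contractility_scale * params.emax_lv * dv
    if params.ed_b_lv > 0.0:
        p_ed = params.ed_a_lv * np.expm1(params.ed_b_lv * dv)
    else:
        p_ed = params.emin_lv * dv
    return act * p_es + (1.0 - act) * p_ed


def _pressures(v, params: CVSParams, t_in_cycle, e_rv=None):
    if e_rv is None:
        e_rv = elastance(t_in_cycle, params, "rv")
    p_lv = lv_pressure(t_in_cycle, v[0], params)
    p_la = (v[1] - params.v0_la) / params.c_la
    p_rv = e_rv * (v[2] - params.v0_rv)
    p_ra = (v[3] - params.v0_ra) / params.c_ra
    p_ao = (v[4] - params.v0_ao) / params.c_ao
    p_sv = (v[5] - params.v0_sv) / params.c_sv
    p_pa = (v[6] - params.v0_pa) / params.c_pa
    p_pv = (v[7] - params.v0_pv) / params.c_pv
    return p_lv, p_la, p_rv, p_ra, p_ao, p_sv, p_pa, p_pv


def cvs_rhs(t_in_cycle, y, params: CVSParams, q_pump_mls: float,
            av_open: bool = False):
    """Compartmental mass balances (mL/s) plus the aortic-valve flow ODE.

    ``y`` holds the eight volumes and the aortic-valve flow ``q_av``;
    ``q_pump_mls`` is the pump flow withdrawn from the left ventricle
    and injected into the aorta (may be negative for backflow).  The
    three inlet valves are ideal diodes: flow = max(0, ΔP)/R.  The
    aortic valve obeys ``l_av·dq/dt = ΔP − r_av·q`` while open and is
    clamped shut otherwise (mode switching is the caller's job).
    """
    p_lv, p_la, p_rv, p_ra, p_ao, p_sv, p_pa, p_pv = _pressures(y[:8], params, t_in_cycle)

    if av_open:
        q_av = y[8]
        dq_av = (p_lv - p_ao - params.r_av * q_av) / params.l_av
    else:
        q_av = 0.0
        dq_av = 0.0
    q_mv = max(0.0, p_la - p_lv) / params.r_mv
    q_sys = (p_ao - p_sv) / (params.r_sys * params.svr_scale)
    q_vr = (p_sv - p_ra) / params.r_vr
    q_tv = max(0.0, p_ra - p_rv) / params.r_tv
    q_pvv = max(0.0, p_rv - p_pa) / params.r_pv
    q_pul = (p_pa - p_pv) / params.r_pul
    q_pla = (p_pv - p_la) / params.r_pvr

    return (
        q_mv - q_av - q_pump_mls,          # lv
        q_pla - q_mv,                      # la
        q_tv - q_pvv,                      # rv
        q_vr - q_tv,                       # ra
        q_av + q_pump_mls - q_sys,         # ao
        q_sys - q_vr,                      # sv
        q_pvv - q_pul,                     # pa
        q_pul - q_pla,                     # pv
        dq_av,
    )


def initial_state(params: CVSParams, pump_attached: bool = True) -> np.ndarray:
    """Build a physiologically plausible initial state (start of diastole).

    Runs discard a transient before metrics are taken, so only rough
    plausibility matters.  The implied total blood volume is conserved
    thereafter (closed circulation).
    """
    p0 = dict(lv=10.0, la=13.0, rv=5.0, ra=7.0, ao=68.0,
              sv=params.init_p_sv, pa=19.0, pv=params.init_p_pv)
    if params.ed_b_lv > 0.0:
        v_lv0 = params.v0_lv + math.log1p(p0["lv"] / params.ed_a_lv) / params.ed_b_lv
    else:
        v_lv0 = params.v0_lv + p0["lv"] / params.emin_lv
    v = [
        v_lv0,
        params.v0_la + p0["la"] * params.c_la,
        params.v0_rv + p0["rv"] / params.emin_rv,
        params.v0_ra + p0["ra"] * params.c_ra,
        params.v0_ao + p0["ao"] * params.c_ao,
        params.v0_sv + p0["sv"] * params.c_sv,
        params.v0_pa + p0["pa"] * params.c_pa,
        params.v0_pv + p0["pv"] * params.c_pv,
    ]
    return np.array(v + [0.0, 0.0, 0.0])  # q_av, pump flow, sensitivity


def total_volume(y) -> float:
    """Total blood volume, mL (conserved by the closed circulation)."""
    return float(np.sum(np.asarray(y)[..., :8], axis=-1))


# ---------------------------------------------------------------------------
# per-cycle metrics

@dataclass(frozen=True)
class CycleMetrics:
    """Aggregates of one post-transient cardiac cycle."""

    cycle_index: int
    Q_AV: float       #: integrated aortic-valve flow, mL/beat
    Q_P: float        #: cycle-mean pump flow, L/min
    Q_T: float        #: cycle-mean total (valve + pump) flow, L/min
    av_open: bool     #: ground-truth label: Q_AV > THRESHOLD_AV
    omega: float      #: commanded speed during the cycle, rpm


def label_av_state(metrics: CycleMetrics) -> str:
    """Ground-truth pumping state: 'PS' iff Q_AV > THRESHOLD_AV, else 'FS'.

    The boundary value itself counts as full support (strict inequality).
    """
    return "PS" if metrics.Q_AV > THRESHOLD_AV else "FS"


# ---------------------------------------------------------------------------
# coupled simulation

@dataclass
class CoupledRun:
    """Waveforms and per-cycle metrics of one coupled simulation."""

    waves: pd.DataFrame
    cycles: list[CycleMetrics]
    final_state: np.ndarray
    final_av_open: bool
    params: CVSParams
    pump: PumpParams | None
    collapsed: bool = False
    samples_per_cycle: int = 0

    def pump_signal(self, start=None, stop=None) -> PumpSignal:
        """View of the run as a PumpSignal (slice by sample index)."""
        df = self.waves.iloc[start:stop]
        return PumpSignal(
            t=df["t"].to_numpy(), H=df["H"].to_numpy(),
            omega=df["omega"].to_numpy(), Q=df["Q_pump"].to_numpy(),
            dQdt=df["dQdt"].to_numpy(), dQdomega=df["dQdomega"].to_numpy(),
        )

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.cycles])


def _integrate_one_cycle(params, pump, omega, y, av_open, t_grid,
                         rtol, atol):
    """Integrate one cardiac cycle with exact aortic-valve events.

    Returns (y_end, av_open_end, Y) with Y sampled on t_grid.
    """
    T = params.period
    t = 0.0
    chunks_t: list[np.ndarray] = []
    chunks_y: list[np.ndarray] = []
    guard = 0

    def rhs(ti, yy, _open=None):
        q_pump = (yy[IDX_Q] * ML_S_PER_L_MIN) if pump is not None else 0.0
        d = cvs_rhs(ti, yy, params, q_pump, av_open=_open)
        if pump is not None:
            p_lv = lv_pressure(ti, yy[0], params)
            p_ao = (yy[4] - params.v0_ao) / params.c_ao
            H = p_ao - p_lv
            dq = pump_rhs(pump, yy[IDX_Q], omega, H)
            ds = sensitivity_rhs(pump, yy[IDX_Q], yy[IDX_S], omega, H)
        else:
            dq = ds = 0.0
        return (*d, dq, ds)

    while t < T - 1e-12:
        if av_open:
            def event(ti, yy):   # closure: aortic flow reverses
                return yy[IDX_QAV]
            event.terminal = True
            event.direction = -1
        else:
            def event(ti, yy):   # opening: forward pressure gradient
                p_lv = lv_pressure(ti, yy[0], params)
                p_ao = (yy[4] - params.v0_ao) / params.c_ao
                return p_lv - p_ao
            event.terminal = True
            event.direction = 1
        t_eval = t_grid[t_grid >= t]
        sol = solve_ivp(lambda ti, yy: rhs(ti, yy, _open=av_open),
                        (t, T), y, method="LSODA", t_eval=t_eval,
                        events=event, rtol=rtol, atol=atol)
        if not (sol.success or sol.status == 1):
            raise IntegrationError(f"coupled integration failed: {sol.message}")
        if len(sol.t):   # t_eval may be empty when an event lands after
            chunks_t.append(np.asarray(sol.t))       # the last grid point
            chunks_y.append(np.asarray(sol.y))
        if sol.status == 1 and sol.t_events[0].size:
            y = np.array(sol.y_events[0][0])
            t = float(sol.t_events[0][0])
            if av_open:
                y[IDX_QAV] = 0.0
            av_open = not av_open
        else:
            y = sol.y[:, -1]
            t = T
        guard += 1
        if guard > 40:
            raise IntegrationError("aortic valve chattering: too many events per cycle")

    tt = np.concatenate(chunks_t) if chunks_t else np.empty(0)
    YY = np.concatenate(chunks_y, axis=1) if chunks_y else np.empty((N_STATES, 0))
    # map the sampled chunks back onto t_grid (event times may duplicate
    # a grid point; keep the first occurrence)
    _, keep = np.unique(np.round(tt / (t_grid[1] - t_grid[0])).astype(int),
                        return_index=True)
    Y = YY[:, keep][:, :len(t_grid)]
    if Y.shape[1] < len(t_grid):   # final grid point landed on T exactly
        Y = np.hstack([Y, y[:, None]])[:, :len(t_grid)]
    return y, av_open, Y


def simulate_cycles(
    params: CVSParams,
    pump: PumpParams | None,
    omega_per_cycle: Sequence[float],
    y0: np.ndarray,
    av_open: bool = False,
    t0: float = 0.0,
    cycle_offset: int = 0,
    dt_out: float = 1e-3,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> CoupledRun:
    """Low-level driver: integrate whole cardiac cycles at per-cycle speeds.

    The pump speed is held constant within each cycle (speed commands
    change at cycle boundaries).  The output grid spacing is the nearest
    divisor of the cycle length to ``dt_out``.  With ``pump=None`` the
    pump branch is clamped (no device attached).
    """
    T = params.period
    n_sub = max(2, round(T / dt_out))
    dt = T / n_sub
    t_grid = np.linspace(0.0, T, n_sub + 1)   # exact endpoints

    rows_t, rows_y, rows_w = [], [], []
    y = np.array(y0, dtype=float)
    collapsed = False
    for k, omega in enumerate(omega_per_cycle):
        y, av_open, Y = _integrate_one_cycle(
            params, pump, float(omega), y, av_open, t_grid, rtol, atol)
        if Y[:8].min() < 0.0:
            collapsed = True
            msg = ("compartment volume went negative "
                   f"(cycle {cycle_offset + k}): ventricular collapse")
            if params.on_collapse == "raise":
                raise VentricularCollapseError(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        rows_t.append(t0 + k * T + t_grid[:-1])
        rows_y.append(Y[:, :-1])
        rows_w.append(np.full(n_sub, float(omega)))

    t = np.concatenate(rows_t)
    Y = np.concatenate(rows_y, axis=1)
    w = np.concatenate(rows_w)
    waves = _waveform_frame(t, Y, w, params, pump)
    cycles = _cycle_metrics(waves, n_sub, dt, cycle_offset, list(omega_per_cycle))
    return CoupledRun(waves=waves, cycles=cycles, final_state=y,
                      final_av_open=av_open, params=params, pump=pump,
                      collapsed=collapsed, samples_per_cycle=n_sub)


def _waveform_frame(t, Y, w, params: CVSParams, pump) -> pd.DataFrame:
    t_in_cycle = np.mod(t - t[0], params.period)
    p = _pressures(Y[:8], params, t_in_cycle)
    p_lv, p_la, p_rv, p_ra, p_ao, p_sv, p_pa, p_pv = p
    q_av = np.maximum(0.0, Y[IDX_QAV])
    q_mv = np.maximum(0.0, p_la - p_lv) / params.r_mv
    Q = Y[IDX_Q]
    H = p_ao - p_lv
    if pump is not None:
        dQdt = np.asarray(pump_rhs(pump, Q, w, H), dtype=float)
    else:
        dQdt = np.zeros_like(Q)
    cols = {
        "t": t, "P_lv": p_lv, "P_la": p_la, "P_rv": p_rv, "P_ra": p_ra,
        "P_ao": p_ao, "P_sv": p_sv, "P_pa": p_pa, "P_pv": p_pv,
        "Q_av": q_av, "Q_mv": q_mv, "H": H, "omega": w,
        "Q_pump": Q, "dQdt": dQdt, "dQdomega": Y[IDX_S],
        "V_total": Y[:8].sum(axis=0),
    }
    for name, vi in zip(COMPARTMENTS, Y[:8]):
        cols[f"V_{name}"] = vi
    return pd.DataFrame(cols)


def _cycle_metrics(waves, n_sub, dt, cycle_offset, omegas) -> list[CycleMetrics]:
    out = []
    q_av = waves["Q_av"].to_numpy()
    q_pump = waves["Q_pump"].to_numpy()
    for k, omega in enumerate(omegas):
        sl = slice(k * n_sub, (k + 1) * n_sub)
        av_ml = float(np.sum(q_av[sl]) * dt)                  # mL/beat
        qp = float(np.mean(q_pump[sl]))                        # L/min
        qt = float(np.mean(q_av[sl] + q_pump[sl] * ML_S_PER_L_MIN) / ML_S_PER_L_MIN)
        out.append(CycleMetrics(
            cycle_index=cycle_offset + k, Q_AV=av_ml, Q_P=qp, Q_T=qt,
            av_open=av_ml > THRESHOLD_AV, omega=float(omega),
        ))
    return out


def run_coupled(
    params: CVSParams,
    pump: PumpParams | None,
    speed_profile,
    duration_cycles: int,
    transient_cycles: int = 5,
    y0: np.ndarray | None = None,
    dt_out: float = 1e-3,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> CoupledRun:
    """Co-integrate the circulation and the pump for whole cardiac cycles.

    ``speed_profile`` is a constant (rpm), a per-cycle sequence, or a
    callable cycle_index -> rpm.  The first ``transient_cycles`` cycles
    are simulated but excluded from the returned metrics and waveforms.
    """
    if duration_cycles < 5:
        raise ValueError("duration_cycles must be at least 5")
    if callable(speed_profile):
        omegas = [float(speed_profile(k)) for k in range(duration_cycles)]
    elif np.isscalar(speed_profile):
        omegas = [float(speed_profile)] * duration_cycles
    else:
        omegas = [float(w) for w in speed_profile]
        if len(omegas) != duration_cycles:
            raise ValueError("speed profile length must equal duration_cycles")
    if y0 is None:
        y0 = initial_state(params, pump_attached=pump is not None)

    run = simulate_cycles(params, pump, omegas, y0, dt_out=dt_out,
                          rtol=rtol, atol=atol)
    if transient_cycles:
        n_sub = run.samples_per_cycle
        run.waves = run.waves.iloc[transient_cycles * n_sub:].reset_index(drop=True)
        run.cycles = run.cycles[transient_cycles:]
    return run
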