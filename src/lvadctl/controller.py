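"""Dual-objective pump speed controller.

The controller pursues two conflicting goals and alternates between
them:

* **flow control** — drive the estimated pump flow ``Q_P`` (the pump
  model's flow integrated over a five-cycle epoch, expressed in L/min)
  to the desired level ``Q_D`` by stepping the speed up 200 rpm per
  epoch;
* **pumping-state control** — keep the aortic valve opening.  While
  ramping, the detection index I_AV is evaluated each epoch; a
  confirmed index reversal marks the transition to full support.  The
  speed at the transition is stored, held for ten cardiac cycles
  (``FS_HOLD``), then dropped 10 % below the stored value for another
  ten cycles (``PS_HOLD``) so the valve reopens.  The two levels then
  alternate — a "semi-physiological" flow pattern — until the estimated
  flow at the high level falls short of the target, which restarts the
  ramp.

The estimation unit never reads the circulation model's true pump flow:
it re-integrates the pump model from the measured pressure head and the
commanded speed, exactly as a physical controller with a differential
pressure sensor would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cvs import CVSParams, CycleMetrics, initial_state, simulate_cycles
from .detection import IndexValue, compute_index
from .exceptions import LvadCtlError
from .pump import PumpParams, integrate_pump

log = logging.getLogger(__name__)

SEEK, FS_HOLD, PS_HOLD = "SEEK", "FS_HOLD", "PS_HOLD"


@dataclass
class ControllerConfig:
    """Tunable controller constants (defaults follow the control scheme)."""

    q_d: float = 4.0              #: desired pump flow, L/min
    step_rpm: float = 200.0       #: SEEK speed increment per epoch
    epoch_cycles: int = 5         #: cycles per SEEK evaluation epoch
    hold_cycles: int = 10         #: dwell of FS_HOLD and PS_HOLD
    drop_fraction: float = 0.9    #: PS_HOLD speed = drop_fraction * stored
    omega_min: float = 4000.0
    omega_max: float = 10000.0
    initial_omega: float = 5000.0
    reseek_margin: float = 0.1    #: re-seek when FS_HOLD Q_P < Q_D - margin
    #: transition speed to store: "confirmed" (the step at which the index
    #: reversal is confirmed, one step above the extremum; default) or
    #: "extremum" (the extremum step itself).  The ramp only passes the
    #: extremum because the flow target was not yet met there, so holding at
    #: the extremum re-triggers seeking; the confirmed step is the lowest
    #: speed at which the controller has observed full support.
    stored_speed: str = "confirmed"


@dataclass
class ControllerState:
    """Mutable controller state advanced once per epoch/hold phase."""

    mode: str = SEEK
    omega_cmd: float = 5000.0
    omega_stored: float | None = None
    q_p: float = 0.0                       #: last epoch-mean estimated flow
    epoch_cycles_elapsed: int = 0
    index_history: list[IndexValue] = field(default_factory=list)
    saturated: bool = False
    q_est_last: float = 0.0                #: estimator's terminal flow, L/min


@dataclass
class EpochSummary:
    """One controller decision epoch."""

    cycle_start: int
    cycle_span: int
    mode: str
    omega: float
    Q_P: float                 #: estimated pump flow over the epoch, L/min
    I_AV: float | None


def flow_decision(state: ControllerState, cfg: ControllerConfig) -> bool:
    """Flow-control branch at a SEEK epoch boundary.

    Returns True when the speed was stepped up (estimated flow below
    target); False hands control to the pumping-state branch.
    """
    if state.q_p < cfg.q_d:
        new = min(state.omega_cmd + cfg.step_rpm, cfg.omega_max)
        if new == state.omega_cmd:
            if not state.saturated:
                log.warning("speed saturated at %.0f rpm with Q_P=%.2f < Q_D=%.2f",
                            new, state.q_p, cfg.q_d)
            state.saturated = True
        state.omega_cmd = new
        return True
    return False


def _online_reversal(history: list[IndexValue], model_id: str):
    """Confirmed index reversal on the strictly ascending part of history.

    Returns the IndexValue at the extremum, or None.  Samples taken
    while holding speed (equal omega) are ignored so solver-level jitter
    cannot fake a reversal.
    """
    asc = []
    for iv in history:
        if asc and iv.omega_at_eval <= asc[-1].omega_at_eval:
            continue
        asc.append(iv)
    for i in range(2, len(asc)):
        before = asc[i - 1].I_AV - asc[i - 2].I_AV
        after = asc[i].I_AV - asc[i - 1].I_AV
        if model_id == "S1" and before < 0 and after > 0:
            return asc[i - 1], asc[i]
        if model_id == "S2" and before > 0 and after < 0:
            return asc[i - 1], asc[i]
    return None


def state_decision(state: ControllerState, cfg: ControllerConfig,
                   model_id: str) -> None:
    """Pumping-state branch: enter the hold alternation on FS detection.

    Called at a SEEK epoch boundary when the flow target is met.  If the
    index history shows a confirmed reversal, the transition speed is
    stored and the controller enters FS_HOLD; otherwise the speed is
    held (partial support with the target met is the ideal state).
    """
    found = _online_reversal(state.index_history, model_id)
    if found is None:
        return
    extremum, at_detect = found
    stored = extremum.omega_at_eval if cfg.stored_speed == "extremum" \
        else at_detect.omega_at_eval
    state.omega_stored = float(stored)
    low = cfg.drop_fraction * state.omega_stored
    if low < cfg.omega_min:
        log.warning("PS_HOLD speed %.0f rpm clamped to omega_min=%.0f",
                    low, cfg.omega_min)
    state.mode = FS_HOLD
    state.omega_cmd = state.omega_stored
    state.index_history.clear()


@dataclass
class ClosedLoopResult:
    """Full trace of a closed-loop run."""

    waves: pd.DataFrame
    cycles: list[CycleMetrics]
    epochs: list[EpochSummary]
    mode_per_cycle: list[str]
    config: ControllerConfig
    collapsed: bool = False

    def epochs_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.epochs])

    def metrics_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(m) for m in self.cycles])
        df["mode"] = self.mode_per_cycle[: len(df)]
        return df


def run_closed_loop(
    cvs: CVSParams,
    pump: PumpParams,
    config: ControllerConfig | None = None,
    duration_cycles: int = 120,
    schedule: list[tuple[int, dict]] | None = None,
    settle_cycles: int = 5,
    dt_out: float = 1e-3,
) -> ClosedLoopResult:
    """Run the coupled circulation under closed-loop speed control.

    ``schedule`` applies circulation parameter changes mid-run: a list
    of ``(cycle_index, {field: value})`` entries (e.g. a contractility
    staircase).  The first ``settle_cycles`` cycles run at the initial
    speed before the controller takes over (they are kept in the trace).
    """
    cfg = config or ControllerConfig()
    params = cvs
    state = ControllerState(omega_cmd=cfg.initial_omega)
    schedule = sorted(schedule or [])
    sched_i = 0

    y = initial_state(params)
    av_open = False
    cycle = 0
    waves_parts: list[pd.DataFrame] = []
    all_cycles: list[CycleMetrics] = []
    modes: list[str] = []
    epochs: list[EpochSummary] = []
    collapsed = False
    t_clock = 0.0

    def apply_schedule(pm: CVSParams, upto: int) -> CVSParams:
        nonlocal sched_i
        while sched_i < len(schedule) and schedule[sched_i][0] <= upto:
            pm = pm.with_scenario(**schedule[sched_i][1])
            sched_i += 1
        return pm

    def simulate_block(n_cycles: int, omega: float, mode: str):
        nonlocal y, av_open, cycle, collapsed, t_clock, params
        params = apply_schedule(params, cycle)
        run = simulate_cycles(params, pump, [omega] * n_cycles, y,
                              av_open=av_open, t0=t_clock,
                              cycle_offset=cycle, dt_out=dt_out)
        y, av_open = run.final_state, run.final_av_open
        collapsed = collapsed or run.collapsed
        waves_parts.append(run.waves)
        all_cycles.extend(run.cycles)
        modes.extend([mode] * n_cycles)
        cycle += n_cycles
        t_clock += n_cycles * params.period
        return run

    def estimate(run) -> tuple[float, IndexValue]:
        """Estimation unit: re-integrate the pump model from measured H."""
        sig_meas = run.pump_signal()
        est = integrate_pump(pump, sig_meas.t, sig_meas.H, sig_meas.omega,
                             Q0=state.q_est_last)
        state.q_est_last = float(est.Q[-1])
        n = run.samples_per_cycle
        iv = compute_index(est, cycle_window=slice(len(est.t) - n, None),
                           model_id=pump.model_id, cycle_index=cycle - 1)
        return float(np.mean(est.Q)), iv

    # settle at the initial speed so the estimator starts from a sane state
    if settle_cycles:
        run = simulate_block(settle_cycles, state.omega_cmd, SEEK)
        q_p, _ = estimate(run)
        state.q_p = q_p

    while cycle < duration_cycles:
        if state.mode == SEEK:
            run = simulate_block(min(cfg.epoch_cycles, duration_cycles - cycle),
                                 state.omega_cmd, SEEK)
            q_p, iv = estimate(run)
            state.q_p = q_p
            state.index_history.append(iv)
            epochs.append(EpochSummary(cycle - len(run.cycles), len(run.cycles),
                                       SEEK, state.omega_cmd, q_p, iv.I_AV))
            if not flow_decision(state, cfg):
                state_decision(state, cfg, pump.model_id)
        elif state.mode in (FS_HOLD, PS_HOLD):
            omega = state.omega_cmd if state.mode == FS_HOLD else max(
                cfg.drop_fraction * state.omega_stored, cfg.omega_min)
            n = min(cfg.hold_cycles, duration_cycles - cycle)
            run = simulate_block(n, omega, state.mode)
            q_p, iv = estimate(run)
            epochs.append(EpochSummary(cycle - n, n, state.mode, omega, q_p, iv.I_AV))
            if state.mode == FS_HOLD:
                state.q_p = q_p
                if q_p < cfg.q_d - cfg.reseek_margin:
                    log.info("cycle %d: FS_HOLD flow %.2f below target %.2f; re-seeking",
                             cycle, q_p, cfg.q_d)
                    state.mode = SEEK
                    state.index_history.clear()
                else:
                    state.mode = PS_HOLD
            else:
                state.mode = FS_HOLD
                state.omega_cmd = state.omega_stored
        else:  # pragma: no cover - defensive
            raise LvadCtlError(f"unknown controller mode {state.mode}")

    waves = pd.concat(waves_parts, ignore_index=True)
    return ClosedLoopResult(waves=waves, cycles=all_cycles, epochs=epochs,
                            mode_per_cycle=modes, config=cfg, collapsed=collapsed)
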