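"""Scenario orchestration, accuracy campaigns, fixtures and reporting.

The central job is the open-loop accuracy campaign: for every scenario
setting of three sweep families — contractility (±15 % in 5 % steps),
heart rate (50–110 bpm in 10 bpm steps) and systemic vascular
resistance (−25 % … +50 %) — and for both pump generations, run a
100-rpm speed sweep with five-cycle dwells through the partial-/full-
support transition, detect the transition from the index extremum,
score it against the integrated-aortic-valve-flow ground truth, and
tabulate per-family and per-pump means.

The pipeline is fully deterministic: identical configuration yields
bit-identical metric tables.  (The scenario schema reserves a ``seed``
field for future noise injection; it is currently inert.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cvs import CVSParams, CycleMetrics, initial_state, simulate_cycles
from .detection import (IndexValue, accuracy, compute_index, detect_transition,
                        ground_truth_transition)
from .exceptions import LvadCtlError
from .pump import PumpParams, load_pump_params

log = logging.getLogger(__name__)

#: scenario families and their Table-style setting lists
CONTRACTILITY_SETTINGS = (-15, -10, -5, 0, 5, 10, 15)          # percent
HEART_RATE_SETTINGS = (50, 60, 70, 80, 90, 100, 110)           # bpm
SVR_SETTINGS = (-25, -15, -10, 0, 15, 25, 50)                  # percent

FAMILIES = {
    "contractility": CONTRACTILITY_SETTINGS,
    "heart_rate": HEART_RATE_SETTINGS,
    "svr": SVR_SETTINGS,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the accuracy campaign."""

    family: str
    setting: float
    pump: str = "S1"
    protocol: str = "open_loop_sweep"
    seed: int | None = None     # reserved; no stochastic component exists

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown scenario family {self.family!r}")
        if self.protocol not in ("open_loop_sweep", "closed_loop"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    def cvs_params(self, base: CVSParams | None = None) -> CVSParams:
        base = base or CVSParams()
        if self.family == "contractility":
            return base.with_scenario(contractility_scale=1.0 + self.setting / 100.0)
        if self.family == "heart_rate":
            return base.with_scenario(hr=float(self.setting))
        return base.with_scenario(svr_scale=1.0 + self.setting / 100.0)


@dataclass
class SweepResult:
    """Outcome of one open-loop sweep through the support transition."""

    scenario: ScenarioConfig
    omegas: list[float]
    indices: list[IndexValue]
    metrics: list[CycleMetrics]
    omega_t: float | None = None
    omega_i: float | None = None
    delta_ps: float | None = None
    error: str | None = None


def run_sweep(
    params: CVSParams,
    pump: PumpParams,
    omega_start: float = 4800.0,
    omega_stop: float = 9400.0,
    step: float = 100.0,
    dwell_cycles: int = 5,
    settle_cycles: int = 10,
    stop_margin: float = 800.0,
    dt_out: float = 1e-3,
) -> tuple[list[IndexValue], list[CycleMetrics]]:
    """Open-loop staircase sweep; index and metrics from each dwell's last cycle.

    The sweep ends ``stop_margin`` rpm past the first full-support step
    (enough headroom for the interior-extremum search) or at
    ``omega_stop``.
    """
    y = initial_state(params)
    run = simulate_cycles(params, pump, [omega_start] * settle_cycles, y,
                          dt_out=dt_out)
    y, av_open = run.final_state, run.final_av_open

    indices: list[IndexValue] = []
    metrics: list[CycleMetrics] = []
    first_fs: float | None = None
    omega = omega_start
    while omega <= omega_stop + 1e-9:
        run = simulate_cycles(params, pump, [omega] * dwell_cycles, y,
                              av_open=av_open, dt_out=dt_out)
        y, av_open = run.final_state, run.final_av_open
        n = run.samples_per_cycle
        iv = compute_index(run.pump_signal(start=(dwell_cycles - 1) * n),
                           model_id=pump.model_id)
        indices.append(IndexValue(cycle_index=len(indices),
                                  omega_at_eval=float(omega), I_AV=iv.I_AV))
        metrics.append(run.cycles[-1])
        if first_fs is None and not run.cycles[-1].av_open and len(metrics) > 1:
            first_fs = omega
        if first_fs is not None and omega >= first_fs + stop_margin:
            break
        omega += step
    return indices, metrics


def run_scenario(scenario: ScenarioConfig, base: CVSParams | None = None,
                 **sweep_kwargs) -> SweepResult:
    """Run and score one campaign cell."""
    pump = load_pump_params(scenario.pump)
    params = scenario.cvs_params(base)
    indices, metrics = run_sweep(params, pump, **sweep_kwargs)
    result = SweepResult(scenario=scenario,
                         omegas=[iv.omega_at_eval for iv in indices],
                         indices=indices, metrics=metrics)
    try:
        result.omega_t = ground_truth_transition(metrics)
        result.omega_i = detect_transition(indices, pump.model_id)
        result.delta_ps = accuracy(result.omega_t, result.omega_i)
    except LvadCtlError as exc:
        result.error = f"{type(exc).__name__}: {exc}"
        log.warning("scenario %s/%s %s: %s", scenario.family, scenario.setting,
                    scenario.pump, result.error)
    return result


def run_table3(pumps: Sequence[str] = ("S1", "S2"),
               families: Sequence[str] = tuple(FAMILIES),
               base: CVSParams | None = None,
               **sweep_kwargs) -> pd.DataFrame:
    """Full accuracy campaign: every family setting for every pump.

    Returns a tidy frame with one row per cell (scenario_family,
    setting, pump, omega_t, omega_i, delta_ps, error); family "Overall"
    means and per-pump grand means are appended as summary rows.
    """
    rows = []
    for pump in pumps:
        for family in families:
            for setting in FAMILIES[family]:
                res = run_scenario(ScenarioConfig(family=family,
                                                  setting=setting, pump=pump),
                                   base=base, **sweep_kwargs)
                rows.append(dict(scenario_family=family, setting=setting,
                                 pump=pump, omega_t=res.omega_t,
                                 omega_i=res.omega_i, delta_ps=res.delta_ps,
                                 error=res.error))
                log.info("cell %s/%s %s: omega_t=%s omega_i=%s acc=%s",
                         family, setting, pump, res.omega_t, res.omega_i,
                         res.delta_ps)
    df = pd.DataFrame(rows)
    summaries = []
    for pump in pumps:
        for family in families:
            cells = df[(df.pump == pump) & (df.scenario_family == family)]
            summaries.append(dict(scenario_family=family, setting="Overall",
                                  pump=pump, omega_t=np.nan, omega_i=np.nan,
                                  delta_ps=cells.delta_ps.mean(), error=None))
        cells = df[df.pump == pump]
        summaries.append(dict(scenario_family="all", setting="Grand mean",
                              pump=pump, omega_t=np.nan, omega_i=np.nan,
                              delta_ps=cells.delta_ps.mean(), error=None))
    summary_df = pd.DataFrame(summaries).astype(df.dtypes.to_dict(), errors="ignore")
    return pd.concat([df, summary_df], ignore_index=True)


# ---------------------------------------------------------------------------
# synthetic pressure-head fixtures (pump-layer tests without the circulation)

@dataclass(frozen=True)
class SyntheticHeadWaveform:
    """Parametric pressure-head waveform standing in for the circulation."""

    hr: float = 80.0                 #: bpm
    mean_head: float = 100.0         #: mmHg
    pulse_amplitude: float = 40.0    #: mmHg
    shape: str = "sine"              #: "sine" or "gaussian_systolic_dip"
    duration: float = 7.5            #: s
    omega: float = 9000.0            #: constant speed column, rpm
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.shape not in ("sine", "gaussian_systolic_dip"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        if self.mean_head - self.pulse_amplitude <= 0:
            raise ValueError("head waveform must stay positive")
        if self.duration <= 0 or self.hr <= 0:
            raise ValueError("duration and heart rate must be positive")


def make_fixture(spec: SyntheticHeadWaveform) -> pd.DataFrame:
    """Deterministic (t, H, omega) table for pump-layer unit tests.

    ``sine``: H = mean + A·sin(2π·f·t).  ``gaussian_systolic_dip``: a
    negative Gaussian dip of depth A centred at 30 % of each cycle with
    width 10 % of the cycle (a crude systolic head collapse).
    """
    t = np.arange(0.0, spec.duration, spec.dt)
    T = 60.0 / spec.hr
    phase = np.mod(t, T) / T
    if spec.shape == "sine":
        H = spec.mean_head + spec.pulse_amplitude * np.sin(2 * np.pi * t / T)
    else:
        H = spec.mean_head - spec.pulse_amplitude * np.exp(
            -0.5 * ((phase - 0.3) / 0.1) ** 2)
    return pd.DataFrame({"t": t, "H": H, "omega": np.full_like(t, spec.omega)})


def render_report(table: pd.DataFrame, path=None, plot_path=None) -> pd.DataFrame:
    """Write the campaign table as CSV (stable column order); optional plot."""
    cols = ["scenario_family", "setting", "pump", "omega_t", "omega_i",
            "delta_ps", "error"]
    out = table.reindex(columns=[c for c in cols if c in table.columns])
    if path is not None:
        out.to_csv(path, index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        cells = out[out.setting.apply(lambda s: not isinstance(s, str))]
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
        for ax, fam in zip(axes, FAMILIES):
            sub = cells[cells.scenario_family == fam]
            for pump, grp in sub.groupby("pump"):
                ax.plot(grp.setting, grp.delta_ps, "o-", label=pump)
            ax.set_title(fam)
            ax.set_ylabel("accuracy, %")
            ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# closed-loop scenario staircases

def staircase_schedule(family: str, dwell_cycles: int = 60) -> list[tuple[int, dict]]:
    """Parameter staircase visiting every setting of a scenario family.

    Levels are ordered as in the campaign tables and applied every
    ``dwell_cycles`` cardiac cycles (long enough for at least two full
    controller hold periods per level).
    """
    out = []
    for k, setting in enumerate(FAMILIES[family]):
        if family == "contractility":
            change = {"contractility_scale": 1.0 + setting / 100.0}
        elif family == "heart_rate":
            change = {"hr": float(setting)}
        else:
            change = {"svr_scale": 1.0 + setting / 100.0}
        out.append((k * dwell_cycles, change))
    return out


def run_closed_loop_family(family: str, pump: str = "S1",
                           dwell_cycles: int = 60,
                           base: CVSParams | None = None,
                           config=None):
    """Closed-loop run sweeping a whole scenario family as a staircase."""
    from .controller import run_closed_loop
    from .pump import load_pump_params as _load
    schedule = staircase_schedule(family, dwell_cycles)
    duration = dwell_cycles * len(FAMILIES[family])
    return run_closed_loop(base or CVSParams(), _load(pump), config=config,
                           duration_cycles=duration, schedule=schedule)
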