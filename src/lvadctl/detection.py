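"""Aortic-valve-state detection from pump-model derivative signals.

A scalar index ``I_AV`` is computed once per evaluation epoch from the
product ``p(t) = dQ/dt · dQ/dω`` over the last cardiac cycle of the
epoch.  The two pump generations use different functionals of the
product's per-cycle extrema:

=====  =============================================
pump   index
=====  =============================================
S1     max(p) / (max(p) − min(p))
S2     max(p) − min(p)
=====  =============================================

Across an ascending speed ramp the S1 index passes through a local
minimum, and the S2 index through a local maximum, at the transition
from partial support (aortic valve still opening) to full support
(valve closed); no user-selectable threshold is involved.  Detection
accuracy against the near-zero-aortic-valve-flow ground truth is scored
as ``δ_PS = (1 − |ω_t − ω_i|/1000) · 100 %`` with 1000 rpm the
normalizing speed amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cvs import THRESHOLD_AV, CycleMetrics
from .exceptions import DegenerateSignalError, NoTransitionError, SweepRangeError
from .pump import PumpSignal


@dataclass(frozen=True)
class IndexValue:
    """One detection-index sample (one evaluation epoch)."""

    cycle_index: int
    omega_at_eval: float
    I_AV: float


@dataclass(frozen=True)
class AccuracyRecord:
    """Detection accuracy of one scenario sweep."""

    scenario: str
    omega_t: float      #: true transition speed, rpm
    omega_i: float      #: index-detected transition speed, rpm
    delta_ps: float     #: accuracy, percent


def compute_index(signal: PumpSignal, cycle_window: slice | None = None,
                  model_id: str = "S1", cycle_index: int = -1) -> IndexValue:
    """Evaluate I_AV on one cardiac cycle of a pump signal.

    ``cycle_window`` selects the cycle's samples (default: whole signal).
    The derivative product must not be constant for S1 (the ratio is
    undefined then).
    """
    sl = cycle_window if cycle_window is not None else slice(None)
    p = signal.dQdt[sl] * signal.dQdomega[sl]
    mx = float(np.max(p))
    mn = float(np.min(p))
    if model_id == "S1":
        if mx == mn:
            raise DegenerateSignalError(
                "derivative product constant over the cycle; S1 ratio undefined")
        value = mx / (mx - mn)
    elif model_id == "S2":
        value = mx - mn
    else:
        raise ValueError(f"unknown pump model {model_id!r}")
    omega = float(np.median(signal.omega[sl]))
    return IndexValue(cycle_index=cycle_index, omega_at_eval=omega, I_AV=value)


def _extremum_kind(model_id: str) -> str:
    if model_id == "S1":
        return "min"    # index falls through PS, rises in FS
    if model_id == "S2":
        return "max"    # index rises through PS, falls in FS
    raise ValueError(f"unknown pump model {model_id!r}")


def detect_transition(index_series: Sequence[IndexValue], model_id: str,
                      mode: str = "offline") -> float:
    """Locate the partial-/full-support transition speed from I_AV samples.

    ``index_series`` must be ordered by strictly increasing speed and
    contain at least three points.

    offline
        Returns the speed of the first interior local extremum (minimum
        for S1, maximum for S2) while ascending in omega; on an
        equal-valued plateau the lower speed wins (earlier full-support
        declaration is the safer call).
    online
        Emulates a live ramp: full support is declared at the first
        step whose index value reverses the pre-transition direction
        (rises after falling for S1; falls after rising for S2) for one
        full epoch, and the returned speed is the previous step's.
    """
    if len(index_series) < 3:
        raise NoTransitionError("need at least three index samples")
    omegas = [iv.omega_at_eval for iv in index_series]
    if any(b <= a for a, b in zip(omegas, omegas[1:])):
        raise ValueError("index series must be sorted by increasing omega")
    vals = [iv.I_AV for iv in index_series]
    kind = _extremum_kind(model_id)

    if mode == "offline":
        for i in range(1, len(vals) - 1):
            if kind == "min" and vals[i] < vals[i - 1] and vals[i] <= vals[i + 1]:
                return omegas[i]
            if kind == "max" and vals[i] > vals[i - 1] and vals[i] >= vals[i + 1]:
                return omegas[i]
        raise NoTransitionError("no interior index extremum in the sweep")
    if mode == "online":
        for i in range(2, len(vals)):
            before = vals[i - 1] - vals[i - 2]
            after = vals[i] - vals[i - 1]
            if kind == "min" and before < 0 and after > 0:
                return omegas[i - 1]
            if kind == "max" and before > 0 and after < 0:
                return omegas[i - 1]
        raise NoTransitionError("no confirmed index reversal during the ramp")
    raise ValueError(f"unknown detection mode {mode!r}")


def accuracy(omega_t: float, omega_i: float) -> float:
    """Detection accuracy δ_PS in percent.

    ``δ_PS = (1 − |ω_t − ω_i| / 1000) · 100``, clamped to [0, 100];
    1000 rpm is the normalizing speed amplitude, so every 100 rpm of
    error costs ten percentage points.
    """
    delta = (1.0 - abs(omega_t - omega_i) / 1000.0) * 100.0
    return float(min(100.0, max(0.0, delta)))


def ground_truth_transition(sweep_metrics: Sequence[CycleMetrics]) -> float:
    """True transition speed: lowest swept speed with a closed valve.

    ``sweep_metrics`` holds one post-transient cycle per sweep step,
    ordered by increasing speed; the sweep must start in partial support
    (valve open) and reach full support (integrated valve flow at or
    below :data:`~lvadctl.cvs.THRESHOLD_AV`).
    """
    if not sweep_metrics:
        raise SweepRangeError("empty sweep")
    omegas = [m.omega for m in sweep_metrics]
    if any(b <= a for a, b in zip(omegas, omegas[1:])):
        raise ValueError("sweep metrics must be sorted by increasing omega")
    if not sweep_metrics[0].av_open:
        raise SweepRangeError(
            f"sweep starts in full support at {omegas[0]:.0f} rpm; "
            "extend the sweep downward")
    for m in sweep_metrics:
        if not m.av_open:
            return m.omega
    raise SweepRangeError(
        f"aortic valve still open at {omegas[-1]:.0f} rpm "
        f"(Q_AV={sweep_metrics[-1].Q_AV:.2f} mL > {THRESHOLD_AV} mL); "
        "extend the sweep upward")
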