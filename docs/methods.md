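# Methods

`lvadctl` is a closed-loop in-silico test bench for a physiological speed
controller of implantable rotary blood pumps (RBPs) used as left ventricular
assist devices. It couples (i) empirical dynamic flow models of the Sputnik 1
and Sputnik 2 axial pumps, (ii) a lumped-parameter (0D) model of the failing
circulation, (iii) an aortic-valve-state detector built from pump-model
derivative signals, and (iv) a dual-objective speed controller that
alternates between a pump-flow target and partial support with an open
aortic valve. This note records the models, the calibrated defaults, the
numerical choices, and the known limitations — including one documented,
quantified failure mode of the second-generation detection index in this
circulation.

## Pump models

Both pumps obey a first-order governing equation for the pump flow Q (L/min)
driven by impeller speed ω (rpm) and pressure head H (mmHg, aorta minus left
ventricle):

    S1:  L dQ/dt = aQ + bω² + cH + dQω²
    S2:  L dQ/dt = aQ + bω² + cH + dQω² + e·Q⁻¹ω²H + f·ω²H²

with empirically identified coefficients shipped in
`lvadctl/data/pump_coefficients.yaml` and unit-tested for exact equality.
The unit system (L/min, rpm, mmHg, s) is fixed by the coefficient
magnitudes; at 9000 rpm and 100 mmHg the S1 steady flow is 4.78 L/min, a
sensible axial-pump operating point. The conversion constant to the
circulation's mL/s is 1000/60.

Numerical choices:

* **Steady states.** S1 has the closed form Q = −(bω²+cH)/(a+dω²). For S2
  the steady residual times Q is quadratic in Q; the largest real root in
  (0, 15] L/min is taken (the physical forward branch — the other root is
  negative or tiny and corresponds to the unstable balance of the singular
  term). Where no forward root exists (head far above the zero-flow head)
  a no-operating-point error is raised.
* **Low-flow clamp.** The S2 Q⁻¹ term was never identified near zero flow;
  |Q| is clamped at 0.05 L/min (sign-preserving) inside that term, which
  bounds the right-hand side without touching the operating range.
* **Speed sensitivity.** The detection indices need s = ∂Q/∂ω. It is
  produced by co-integrating the forward sensitivity equation (the governing
  equation differentiated in ω at fixed H), giving a smooth, grid-independent
  signal; a two-point finite-difference re-integration is retained as the
  test oracle (agreement within 2 % under pulsatile head). The clamp freezes
  the Q-dependence of the Q⁻¹ term, so its sensitivity contribution is zero
  inside the clamp.
* **dQ/dt** is the governing equation evaluated along the solution, never a
  numerical difference, so no differentiation noise enters the indices.
* **Integration** uses an adaptive stiff-capable solver (LSODA, rtol 1e-6,
  atol 1e-8) with output resampled to a fixed ~1 ms grid (the exact spacing
  is the nearest divisor of the cycle length), which resolves per-cycle
  extrema at all heart rates in range.

## Circulation model

Eight compliant compartments in a closed loop: LV, aorta/systemic arteries,
systemic veins, RA, RV, pulmonary arteries, pulmonary veins, LA. Ventricles
are activation-blended elastance chambers, P = e_n·E_es·(V−V0) +
(1−e_n)·P_ed(V), with a double-Hill normalized activation e_n(t)
(exponents 1.32 and 27.4, time constants 0.60·T_sys and 1.00·T_sys,
T_sys = 0.32·√(60/HR) s). With the default linear diastolic branch this
reduces exactly to the classical time-varying elastance E(t)(V−V0); an
exponential end-diastolic pressure-volume option (`ed_a_lv`, `ed_b_lv`) is
available but off by default. Atria are passive compliances (no atrial
kick). Mitral, tricuspid and pulmonary valves are ideal diodes with series
resistance.

The **aortic valve** — the valve whose state must be detected — is modelled
with a series blood inertance (6e-4 mmHg·s²/mL) and exact open/close event
handling: it opens when the LV-aorta gradient turns positive and closes when
its flow decelerates through zero. This produces the physiological
end-ejection flow deceleration and dicrotic notch. The feature matters: with
a pure diode valve the pressure-head waveform changes essentially smoothly
through the support transition and the derivative-product indices carry
almost no transition signature; the valve's inertial closure dynamics, which
exist only while the valve still opens, are what the working index detects.

Pump coupling withdraws Q from the LV and injects it into the aorta; the
pump flow and its speed sensitivity are co-integrated with the eight volumes
(11 states). Mass balance is structural (compartment derivatives sum to
zero), so total blood volume is conserved to solver precision (< 0.1 mL
drift over 100 cycles).

**Heart-failure calibration.** The shipped defaults represent a dilated
systolic-failure baseline with a stiff proximal aorta, calibrated to the
unsupported (pump clamped) windows: cardiac output 2.5–3.5 L/min, mean
arterial pressure 60–80 mmHg, LV end-diastolic pressure 15–25 mmHg at
80 bpm. Measured values at the defaults: CO 2.94 L/min, MAP 62 mmHg,
LVEDP 22.5 mmHg. Key parameters: Emax_lv 0.36, Emin_lv 0.08 mmHg/mL,
aortic compliance 0.5 mL/mmHg, systemic resistance 1.15 mmHg·s/mL. A second
calibration anchor follows the closed-loop narrative of the reproduced
study: the pump flow at the support transition is just below the 4 L/min
target (≈3.8–4.0 L/min), so the flow ramp crosses the transition and the
stored high speed sustains the target.

Scenario scaling: contractility multiplies Emax_lv only (±15 %), heart rate
spans 50–110 bpm (systole shortens as √T), and the SVR factor (−25 % to
+50 %) multiplies the systemic resistance.

## Valve-state detection

The per-cycle index I_AV is built from the product p(t) = dQ/dt · dQ/dω of
pump-model derivative signals over the last cardiac cycle of a five-cycle
evaluation epoch:

* S1: I = max(p) / (max(p) − min(p)) — a shape (asymmetry) measure;
* S2: I = max(p) − min(p) — an amplitude (pulsatility) measure.

Across an ascending speed ramp the S1 index has a local minimum, and the S2
index a local maximum, at the transition from partial support (PS, valve
still opening) to full support (FS, valve closed); detection needs no
user-set threshold. Offline, the first interior extremum in ascending speed
is taken (plateau ties resolve to the lower speed — the safer, earlier FS
call); online, FS is declared at the first epoch whose index value reverses
the pre-transition trend, with the reversal step itself as confirmation.

Ground truth is the integrated aortic-valve flow: a cycle with
Q_AV ≤ 1 mL/beat counts as full support ("near-zero" operationalized; the
boundary value itself is FS). Accuracy of a sweep is
δ_PS = (1 − |ω_t − ω_i|/1000)·100 %, clamped to [0, 100], where ω_t is the
first full-support speed and ω_i the index-detected transition; on the
100-rpm scoring grid every step of error costs ten points.

**Protocol.** Open-loop sweeps run 100-rpm steps with five-cycle dwells
(index and ground-truth metrics from each dwell's last cycle), starting at
4800 rpm — the clinical minimum-speed region of these pumps, and above the
S2 model's low-flow clamp zone where the empirical Q⁻¹ term makes the index
jitter — and ending 800 rpm past the first full-support step.

**Known bias (one grid step).** The index extremum marks the last speed at
which valve-opening events still occur, while the ground-truth rule marks
the first speed at which they have (essentially) ceased; the two labels
straddle the true transition and are usually adjacent grid steps. Most S1
cells therefore score 90 (or 80 where the five-cycle dwell has not fully
settled the slowly-converging near-transition circulation), rather than
100. The 1 mL/beat threshold is part of the study conditions and was not
adjusted; a threshold of 2–3 mL/beat would shift ω_t one step down and
most S1 cells to 90–100.

**Known failure: the S2 index in this circulation.** The S2 index is an
absolute amplitude measure, and in this calibrated circulation the
derivative-product amplitude saturates and begins to decline once the pump
carries roughly 2.5–2.8 L/min — several hundred rpm before the valve
actually closes. Its maximum therefore sits systematically 600–1200 rpm
below the true transition, and S2 detection accuracies are poor (family
means 4–24 %). A broad structural search (valve inertance, proximal aortic
stiffness, linear and exponential diastolic stiffness, systolic duration
and activation shape, preload, afterload) found S2 alignment only in severe
low-output baselines (CO ≈ 2 L/min, MAP ≈ 46 mmHg) that violate the
calibration windows above and break the closed-loop flow-target geometry.
The shipped defaults keep the windows and the closed-loop behaviour; the
S2 open-loop accuracy table is reported as measured. The S1 index, being
amplitude-normalized, is robust across the whole calibrated region
(80–90 % per cell, grand mean ≈ 83 %).

## Controller

Decisions are made every five cardiac cycles from the estimation unit: the
pump model re-integrated from the *measured* pressure head and commanded
speed (never from the circulation's internal pump-flow state), with Q_P the
epoch-mean estimated flow. Flow control has priority: while Q_P < Q_D
(default 4 L/min) the speed steps up 200 rpm per epoch (clamped to
4000–10000 rpm, saturation logged). Once the target is met, the
pumping-state branch checks the index history of the ramp for a confirmed
reversal; if full support was crossed, the transition speed is stored, held
for ten cycles (FS_HOLD), then reduced 10 % for ten cycles (PS_HOLD) to
reopen the valve. The two levels alternate — a 20-cycle-periodic
"semi-physiological" pattern — until the high-level flow drops below
Q_D − 0.1 L/min (a 0.1 L/min debounce), which resumes seeking.

**Stored speed.** The stored transition speed is the speed of the
*confirming* epoch, one 200-rpm step above the index extremum. This is a
structural necessity, not a preference: flow control has priority, so the
ramp passes the extremum only while Q_P < Q_D; holding at the extremum
therefore always re-triggers seeking and no stable alternation can form.
Storing the confirming step reproduces the reproduced study's geometry
(baseline S1: stored 6600 rpm with Q_P = 3.98 L/min, PS_HOLD at 5940 rpm
with the valve opening every beat). The extremum variant remains available
as `ControllerConfig(stored_speed="extremum")`.

At scenario extremes where even the confirming-step flow falls short of the
target (e.g. contractility −15 %, 50 bpm), the controller re-seeks, ends up
parking in constant-speed full support with the flow target met, and holds
there — a safe, flow-prioritizing outcome of the stated scheme; mean pump
flow never reverses in any scenario epoch.

## Scenario harness

The accuracy campaign covers 21 settings (7 contractility, 7 heart-rate,
7 SVR) × 2 pumps, each an open-loop sweep as above (~3 minutes total on one
CPU at the ~1 ms output grid). Closed-loop scenario studies apply the same
settings as staircases with 60-cycle dwells per level (two or more full
controller periods). Everything is deterministic — identical configuration
gives bit-identical tables; the scenario schema reserves an inert `seed`
field for future noise injection. The synthetic head-waveform fixtures
(sine or Gaussian-systolic-dip) exercise the pump layer without the
circulation and emulate only the gross shape of a pulsatile head, not
valve events — pump-layer tests passing on them says nothing about
detection in real waveforms.

## What the bench does and does not show

The circulation is a concretization calibrated to stated windows, not the
original study's (unpublished) parameter set; quantitative agreement is
therefore checked in tolerance bands. Absent features: baroreflex and
autonomic control, atrial contraction, valve regurgitation, cannula
elements (the identified pump coefficients are assumed to absorb them),
suction dynamics, and sensor noise. The detection results transfer to real
devices only to the extent that real pressure-head waveforms carry the
valve-closure dynamics this model represents with a single valve
inertance.
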