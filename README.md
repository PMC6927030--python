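# lvadctl

A closed-loop in-silico test bench for physiological speed control of rotary
blood pumps (RBPs) used as left ventricular assist devices. It is aimed at
researchers in medical-device control and cardiovascular modelling who want
to study — without bench or animal experiments — how a speed controller can
hold a pump-flow target **and** keep the native aortic valve opening, using
nothing but signals available on the pump (pressure head and speed).

The bench couples four pieces:

* **Pump models** — first-order dynamic flow models of the Sputnik 1 and
  Sputnik 2 axial pumps,

      S1:  L·dQ/dt = aQ + bω² + cH + dQω²
      S2:  L·dQ/dt = aQ + bω² + cH + dQω² + e·Q⁻¹ω²H + f·ω²H²

  (Q pump flow in L/min, ω speed in rpm, H pressure head in mmHg), with the
  published coefficient sets shipped as package data.
* **Circulation** — an 8-compartment lumped-parameter model of the failing
  circulation (time-varying-elastance ventricles, passive atria, diode
  valves, and an aortic valve with inertance and exact opening/closure
  events), calibrated to a dilated heart-failure baseline (unsupported
  CO ≈ 2.9 L/min, MAP ≈ 62 mmHg, LVEDP ≈ 22 mmHg at 80 bpm).
* **Valve-state detection** — a per-cycle index
  I_AV built from the product dQ/dt · dQ/dω of pump-model derivative
  signals: S1 uses max(p)/(max(p)−min(p)) and detects the transition from
  partial to full support at a local *minimum* across a speed ramp; S2 uses
  max(p)−min(p) and a local *maximum*. Detection accuracy against the
  integrated-aortic-valve-flow ground truth is scored as
  δ_PS = (1 − |ω_t − ω_i|/1000)·100 %.
* **Controller** — every five heart cycles: if the estimated pump flow Q_P
  is below the desired Q_D, step the speed +200 rpm; otherwise maintain
  partial support, storing the speed at the detected full-support
  transition, holding it ten cycles, then dropping 10 % for ten cycles so
  the valve reopens, and alternating between the two levels.

See `docs/methods.md` for the models, calibration, numerical choices and
known limitations (including a documented failure mode of the S2 amplitude
index in this circulation).

## Worked example

Run the closed-loop controller on the Sputnik 1 pump at the heart-failure
baseline with a 4 L/min flow target:

```python
from lvadctl import CVSParams, ControllerConfig, load_pump_params, run_closed_loop

res = run_closed_loop(CVSParams(), load_pump_params("S1"),
                      ControllerConfig(q_d=4.0), duration_cycles=150)
print(res.epochs_frame().tail(6).to_string(index=False))
```

```
 cycle_start  cycle_span    mode  omega      Q_P     I_AV
          95          10 FS_HOLD 6600.0 3.975940 0.470845
         105          10 PS_HOLD 5940.0 3.110234 0.473795
         115          10 FS_HOLD 6600.0 3.975938 0.470847
         125          10 PS_HOLD 5940.0 3.110230 0.473795
         135          10 FS_HOLD 6600.0 3.975940 0.470846
         145           5 PS_HOLD 5940.0 3.100744 0.473672
```

After ramping from 5000 rpm in 200-rpm steps, the controller detects the
transition to full support, stores 6600 rpm, and locks into the 20-cycle
alternation: ten cycles at 6600 rpm delivering the ≈4 L/min target with the
valve closed, then ten cycles at 5940 rpm (10 % below the stored speed)
during which the aortic valve opens every beat — the "semi-physiological"
flow pattern that trades a small flow deficit for regular valve opening.

The same studies are available from the shell:

```bash
lvadctl sweep --pump s1 --family svr -o results/       # open-loop accuracy table
lvadctl closedloop --pump s1 --family contractility    # staircase + controller
lvadctl calibrate                                      # baseline window check
```

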