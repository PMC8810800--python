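# bacnavsim

Simulation platform for evaluating engineered **bacterial voltage-gated
sodium channels (BacNav)** as a cardiac gene therapy, in silico. Bacterial
Na channels are small enough (~0.8 kb) to fit in AAV vectors, unlike
mammalian Na_v1.5; expressing them in cardiomyocytes adds depolarizing
current that can restore excitability and conduction lost to Na-channel
deficiency or fibrosis. This package couples a fitted two-gate kinetic
model of the h2SheP channel to published adult ventricular myocyte models
and exercises the combination in single cells, 1D cables, 2D fibrotic
tissue, and a transmural Brugada-syndrome fiber with a pseudo-ECG readout.

It is intended for cardiac-electrophysiology modelers who want to
reproduce or extend the in-silico arm of the BacNav therapy evaluation:
dose–response of AP metrics, conduction-velocity (CV) rescue, conduction
block in fibrotic substrates, and normalization of Brugada ECG morphology.

## The model

BacNav gating (mV, ms):

```
dm/dt = (m∞ − m)/τ_m        m∞ = 1 / (1 + exp((−22.5 − V)/2.704))
dh/dt = (h∞ − h)/τ_h        h∞ = 1 / (1 + exp((V + 77.05)/10.64))

τ_m = 34.65 / (exp((V+43.47)/14.36) + exp(−(V+15.75)/0.2351)) + 1.66
τ_h = 107.8 / (exp((V+27.15)/0.1281) + exp(−(V+25.63)/25.19)) + 9.593

I_BacNav = X · ḡ_1X · m · h² · (V − E_Na)      [µA/µF]
```

`X` is the expression multiplier; the **1X level is defined by
calibration**: ḡ_1X is the conductance whose simulated peak voltage-clamp
current magnitude equals the endogenous Na_v1.5 peak in the same host
model (holding −80 mV, 500 ms steps −50…+50 mV). Hosts: the O'Hara–Rudy
human ventricular model and a Luo–Rudy-lineage guinea-pig model (plus a
two-variable toy cell for solver verification). Tissue is a monodomain
reaction–diffusion system with `D = a/(2·R_i·C_m)` from the 10 µm fiber
radius and 0.4 kΩ·cm resistivity; fibrosis is modeled by seeded random (or
vertically elongated) nonconducting obstacle nodes whose conductive
connections are severed. See `docs/methods.md` for every assumption and
numerical choice.

## Worked example

Calibrate the channel, then ask whether 1X expression rescues conduction
in a cable whose endogenous Na current is halved:

```python
from bacnavsim import build_cell, calibrate_1x
from bacnavsim.cable1d import CableConfig, run_cable

report = calibrate_1x(build_cell("human"))
print(f"gbar_1x = {report.gbar_1x:.2f} mS/uF, "
      f"peak match {report.mismatch_pct:+.2f}%")

sick = run_cable(CableConfig(gNa_scale=0.5, prepace_beats=20))
print("50% gNa, 0X BacNav:", "block" if sick.blocked
      else f"{sick.cv_cm_s:.1f} cm/s")

treated = run_cable(CableConfig(gNa_scale=0.5, x_level=1.0,
                                gbar_1x=report.gbar_1x, prepace_beats=20))
print("50% gNa, 1X BacNav:", "block" if treated.blocked
      else f"{treated.cv_cm_s:.1f} cm/s")
```

prints

```
gbar_1x = 17.94 mS/uF, peak match -0.01%
50% gNa, 0X BacNav: block
50% gNa, 1X BacNav: 43.3 cm/s
```

i.e. halving Na_v1.5 blocks 1D propagation outright, and 1X BacNav
restores conduction at a healthy-range velocity (the untreated healthy
cable runs at 43.0 cm/s in this framework). The same machinery drives the
2D experiments:

```bash
bacnavsim tissue --fraction 0.15 --pattern random --x-level 0.5 --seed 7
bacnavsim brugada --severity severe --x-level 0.5
bacnavsim reproduce-fig5 --outdir runs/fig5    # every canonical config
```

Each run directory contains `summary.json` (CV, activated fraction, AP
features…), CSV grids/traces, and a `manifest.json` recording seeds,
config hash and runtimes. Canonical experiment configurations live under
`configs/`.

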