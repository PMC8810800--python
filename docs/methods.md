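# Methods

`bacnavsim` simulates the electrophysiological consequences of expressing an
engineered prokaryotic voltage-gated sodium channel (BacNav, the h2SheP
variant of Na_v_SheP D60A) in adult ventricular myocytes and tissue. This
note records the models, the numerical choices, and the design decisions
made where the problem was genuinely open, so that every simulated number
in the README and the test suite can be traced to an explicit assumption.

## The BacNav channel model

The channel is Hodgkin–Huxley gated with one activation gate `m` and
inactivation gating `h`, with fitted voltage dependences (mV, ms):

```
tau_m  = 34.65 / (exp((V+43.47)/14.36) + exp(-(V+15.75)/0.2351)) + 1.66
tau_h  = 107.8 / (exp((V+27.15)/0.1281) + exp(-(V+25.63)/25.19)) + 9.593
m_inf  = 1 / (1 + exp((-22.5 - V)/2.704))
h_inf  = 1 / (1 + exp((V+77.05)/10.64))
```

Salient physiology: activation is half-maximal at −22.5 mV with a steep
slope (2.7 mV), inactivation is half-maximal at −77.05 mV and slow
(τ_h ≈ 9.6 ms at depolarized potentials, versus ≪1 ms for Na_v_1.5), and
both time constants saturate at depolarized potentials (1.66 and 9.593 ms).
The steep exponentials in the τ denominators overflow IEEE doubles at
ordinary potentials; all exponent arguments are clamped to ±700, which is
exact for these asymptotic denominators.

**Current law.** The macroscopic current is ohmic with two identical
inactivation gates:

    I_BacNav = X · ḡ_1X · m · h² · (V − E_rev)

The gate stoichiometry is not determined by the gating fits alone and we
found the choice to be consequential. With a single `h` gate, the fitted
steady-state curves leave an open-probability window m∞·h∞ ≈ 3·10⁻³ near
−15 mV; at the calibrated conductance this produces ~1 µA/µF of sustained
inward current per 0.5X of expression in exactly the voltage range where
the human ventricular model has essentially no inward-rectifier current,
and the cell fails to repolarize (a stable depolarized point near −12 mV)
at any expression level above ≈0.3X. That behavior contradicts the
channel's functional phenotype — its current switches off completely within
tens of milliseconds after the upstroke, stays off during late
repolarization, and expression does not prolong the ventricular AP. The
squared inactivation gate keeps every fitted curve while suppressing the
window open-probability by more than two orders of magnitude; it is the
smallest structural change that makes the channel model consistent with
its documented behavior. (A homotetrameric channel whose inactivation
requires more than one subunit provides the mechanistic reading.)

**Reversal potential.** BacNav is Na-selective; `E_rev` defaults to the
sodium Nernst potential of the host model (≈ +80 mV in the human model
from its intracellular Na, +54 mV in the guinea-pig model with its fixed
Na concentrations) and is configurable.

**Integration.** All Hodgkin–Huxley gates (host and BacNav) advance by the
exact exponential (Rush–Larsen) relaxation `g ← g∞ + (g − g∞)·e^(−dt/τ)`,
which is unconditionally stable and keeps gates in [0, 1] for any step
sequence.

## Host myocyte models

**Human** — the O'Hara–Rudy dynamic adult ventricular model (endocardial
subtype by default; epi/mid scalings available via `celltype`): full fast
and late Na current with CaMK-phosphorylated fractions, transient outward
K current, L-type Ca current with subspace Ca handling, IKr/IKs/IK1, bulk
and subspace Na/Ca exchange, Na/K pump, SR release/uptake, and dynamic
intracellular Na/K/Ca with buffering (41 states + 2 BacNav gates). The
BacNav Na flux is included in the intracellular Na balance. The endocardial
subtype is the default because the source experiments do not state a
subtype; it is a config switch.

**Guinea pig** — a Luo–Rudy-lineage composite: the classic fast Na current
(m³hj), slow inward Ca current with dynamic Cai, and
inward-rectifier/plateau/background K currents, plus the Rudy-lab split of
the delayed rectifier into IKr and IKs (required because the transmural
cable differentiates layers by their IKs:IKr balance) and a transient
outward current Ito = g_to·r³·s·(V−EK). The full dynamic-model Ca subsystem
(JSR/NSR, CICR) is deliberately omitted: none of the reproduced readouts
depend on guinea-pig Ca handling, and a compact, fully-understood host was
preferred over an unverifiable transcription.

The Ito kinetics deserve a note, since the transmural experiments hinge on
them. Activation uses a cubic gate (r³, midpoint −5 mV, slope 9 mV,
τ_r ≤ 10 ms) and inactivation a single gate (midpoint −20 mV, τ_s up to
~90 ms at hyperpolarized potentials). Cubic activation makes phase-1
repolarization self-limiting below ≈−10 mV, which is what renders dome loss
all-or-none: the healthy epicardium (g_to = 0.25 mS/µF) and the mild
Brugada case keep their dome while the severe case loses it. With linear
activation no midpoint reproduces that separation — any Ito strong enough
to carve the notch collapses the dome already at the mild multiplier. The
midpoint sits on the dome-bistability map between "mild retains" and
"severe loses"; the map is steep, so ±3 mV shifts flip individual cases
(this sensitivity is inherent to all-or-none dome dynamics, not to the
implementation).

**Toy model** — a two-variable Aliev–Panfilov excitable cell mapped to the
membrane-potential scale (Vm = 100u − 80), used as the fast fixture for
PDE-level verification (front-speed scaling, conservation, refinement).
Its documented stable region is enforced at construction.

**Charge bookkeeping.** Each kernel returns the instantaneous named
currents along with the total; the integrator uses `dV/dt = −ΣI + I_stim`,
so every registered current enters the membrane equation exactly once
(asserted to round-off in the tests).

## Calibration of the 1X expression level

1X is defined by matching the simulated peak voltage-clamp BacNav current
magnitude to the endogenous Na_v_1.5 peak in the same host: holding
−80 mV, 500 ms steps from −50 to +50 mV in 10 mV increments (the only
protocol the source experiments document), peak = signed extremum within
the step, compared by magnitude. The search is a deterministic bisection
on ḡ (the clamp gates do not depend on ḡ, so the problem is exactly linear
and the bisection is self-verifying). For the human model this yields
ḡ_1X ≈ 17.9 mS/µF against a peak I_Na of ≈ −194 µA/µF.

The calibration is anchored **once, on the human model**, and that ḡ_1X is
reused in the guinea-pig cable. Per-species anchoring was implemented and
rejected: the Luo–Rudy-lineage host has a much larger clamp-peak I_Na
(≈ −394 µA/µF, high availability at −80 mV), and the resulting BacNav dose
overwhelms the transmural AP morphology, destroying the dome-restoration
ordering that the therapy is supposed to produce. `calibrate_1x` remains
available for any host.

## Stimulus and pacing

Single cells are paced with a 1 ms rectangular depolarizing pulse of
80 µA/µF (strongly suprathreshold; a bisection threshold finder is
provided for experiments that need 2× diastolic threshold). Pacing to
equilibrium uses the per-beat criterion "max over state variables of the
relative change < criterion": the production criterion is 0.001 %/beat
with a 200-beat budget; desk-scale runs (tests, acceptance script) use
0.01–0.05 %/beat with 12–30 beats and record the honest convergence flag.
At those budgets the AP metrics are stable to well under 1%, but slow
variables (intracellular Na) are not at their true limit — conduction
velocities change negligibly, which is what the reproduced quantities
depend on.

Rates: human 1 Hz, guinea-pig single cells 3.33 Hz (sinus rates). The
transmural Brugada cable is paced at 2.5 Hz: at 3.33 Hz the composite
host's APD leaves too little diastole for Na-channel recovery and the
untreated Brugada fibers fail to conduct transmurally, contradicting the
reported morphologies; 2.5 Hz is the fastest rate at which every
severity × dose condition conducts.

## 1D cable and 2D tissue

Monodomain reaction–diffusion with
`D = a / (2 R_i C_m)` = 1.25·10⁻³ cm²/ms from the fiber radius (10 µm),
intracellular resistivity (0.4 kΩ·cm) and C_m = 1 µF/cm². Cable: 100 cells
× 100 µm (1 cm), one node per cell (dx = 100 µm, sub-cell refinement
available), no-flux ends, stimulus on the first 3 cells. Tissue: 100 × 100
nodes, dx = dy = 0.01 cm, 5-point stencil with per-edge conductances,
no-flux borders. Obstacle nodes carry no membrane model and every edge
into or out of them is severed (zero conductivity); the symmetric edge
formulation conserves total Vm under pure diffusion to round-off.

Explicit operator splitting: ionic kernel step (Rush–Larsen gates, Euler
concentrations and Vm), then the diffusion increment; dt = 0.01 ms
(diffusion stability limit dx²/4D = 0.02 ms). Halving dt or dx moves the
cable CV by <3%.

**Initial state** is the pre-paced single-cell equilibrium tiled over the
domain; cables run one conditioning beat before the measured beat (the
tiled state is already near the propagating steady state, so further
conditioning changes CV by ≪1%); tissue runs measure the single
corner-initiated beat. Tissue runs stop early when every node has
activated (plus margin) or when no new node has activated for 30 ms
(established block).

**Corner stimulus** is a 15 × 15-node patch (1.5 mm square), 1 ms,
100 µA/µF. The patch size is not documented in the source experiments; a
5 × 5 patch launches a subcritical wave in the 15%-obstacle tissue that
expands ~0.5 cm and collapses, whereas the experiments report sustained
conduction, so the larger patch is used. Homogeneous-tissue CV is
insensitive to the choice (41 cm/s either way).

**Activation time** is the instant of maximum dVm/dt per node, with
crossing of −20 mV defining "activated". Cable CV is the least-squares
slope of position on activation time over the central window (cells
30–70). Block = any node beyond the stimulated region never activating.

**Average 2D CV** coarse-grains the activation map over 5 × 5-node
(0.5 mm) blocks (nan-aware, so obstacle nodes drop out), computes local
front speed 1/|∇T| by central differences on the coarse field, and takes
the median after trimming the top/bottom 5%. Coarse-graining is essential
with obstacles: per-node gradients sample only unobstructed interior
where the front travels at its intrinsic speed and miss the macroscopic
delay of detours entirely (they return the homogeneous value for the 15%
tissue). The estimator is exact on a planar front and within 0.5% on a
circular front; the result varies <7% over block sizes 2–10.

**Obstacle masks**: uniform random nodes without replacement (exactly
`round(fraction·nx·ny)` nodes, seeded), or 1-node-wide vertical strips of
configurable length (default 10 nodes, clipped at borders, overlaps
merged, final strip trimmed to the exact count). The vertical pattern
blocks corner-initiated conduction at 20% coverage without BacNav and
conducts at 1X, reproducing the isthmus source–sink mechanism.

## Transmural Brugada fiber and pseudo-ECG

165 guinea-pig cells: endocardium 1–60 (no Ito, IKs:IKr = 11:1),
midmyocardium 61–105 (Ito 0.2125 mS/µF, 4:1), epicardium 106–165
(Ito 0.25 mS/µF, 35:1), stimulated at the endocardial end. The IKs:IKr
*ratio* is set exactly per layer while the layer's summed
delayed-rectifier conductance is held at the base model's total — the
absolute magnitudes are not published here, and anchoring g_Kr at its
base value instead gives the midmyocardium a quarter of the base
repolarizing conductance and a fiber that cannot follow the pacing rate.

Brugada severity multiplies the fast-inactivation *rates* of the
endogenous Na current (dividing τ_h, leaving h∞ unchanged) and each
layer's Ito conductance: mild (1.5×, 3×), severe (3.5×, 7×).

The pseudo-ECG is the Plonsey–Barr line-source potential at a virtual
electrode on the fiber axis 2 cm beyond the epicardial end,

    φ_e(t) = (a² σ_i / 4 σ_e) Σ_x (−∂Vm/∂x) · (∂(1/r)/∂x) · dx,

evaluated by central differences at 1 kHz. σ_i/σ_e = 1: the conductivities
are not published and the ratio only scales the amplitude; every readout
is a comparison across conditions at fixed scaling. The discrete sum
matches a 20× finer quadrature of the analytic integrand to <1% on a
prescribed Gaussian wave.

**Dome detection**: an AP "has a dome" iff after the phase-1 minimum Vm
re-ascends above 0 mV with the notch ≥5 mV below the secondary maximum,
*or* Vm sustains a plateau above 0 mV for ≥20 ms beyond the spike window.
The second clause covers notchless morphologies (endocardium; treated
fibers where BacNav fills the notch) that plainly retain their plateau.

**ECG deviation** is the sum of absolute differences between two φ_e
traces resampled to a common 1 kHz base. The deviation of a diseased,
treated fiber is measured against the *dose-matched* healthy fiber: the
quantity is meant to isolate the disease's contribution, and a fixed 0X
reference instead conflates it with BacNav's own (benign) morphology
shift, which is present identically in a healthy fiber carrying the same
dose. Under this definition the deviation decreases strictly with dose
for both severities, and severe exceeds mild untreated.

## What the synthetic layer does and does not emulate

The obstacle masks emulate the *geometry* of fibrotic myocardium
(non-conducting area fractions, isotropic speckle vs. elongated
interstitial strips) but not fibroblast coupling, heterogeneous fibrosis
density, or myocyte disarray. The toy cell verifies the PDE machinery
(conservation, front-speed scaling, refinement) but has no ionic
interpretation. Passing tests therefore certify the numerical platform
and the qualitative rescue phenomenology on published ionic models; they
do not certify predictions about real fibrotic tissue beyond what those
models encode.

## Known limitations

- The 15%-random-obstacle tissue conducts at ≈25 cm/s here versus the
  reported ≈34 cm/s (homogeneous: 41 vs 44). On this discrete 4-neighbor
  lattice with every obstacle edge fully severed, single-node corridors
  impose source–sink delays near the conduction-safety limit; the
  original implementation (unpublished) evidently penalized constrictions
  less. The dose response is unaffected (CV strictly increasing with
  BacNav dose, ≈44 cm/s at 2X), but absolute obstacle-tissue CVs sit
  below the reported values.
- The composite guinea-pig host's repolarization is more sensitive to
  Ito and BacNav than the full dynamic model; transmural APD ordering
  (M-cells longest) is not reproduced, and dome bistability boundaries
  are steep.
- Desk-scale pre-pacing (≤30 beats) leaves slow Na accumulation
  incomplete; all reported quantities were checked to be insensitive to
  this at the <1% level except absolute APDs (few-ms drift).
- The voltage-clamp engine replays arbitrary step protocols but no
  Markov-state channel models, temperature corrections, or drug block.
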