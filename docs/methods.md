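# Methods

## Scope and structure

`dualvent` models the expiratory (and, necessarily, inspiratory) fluid
dynamics of two passive patients sharing one pressure-controlled
ventilator through a valved splitter circuit. Two models coexist:

* a **nonlinear lumped hydraulic network** (the workhorse): ventilator
  pressure sources behind check valves, tube segments with turbulent
  friction and elastic walls, quadratic valve/filter losses, a threshold
  valve on one expiratory branch, and two spring–damper–piston lungs;
* a **linear two-compartment discharge model** (the reference): the
  coupled RC pair sharing the exhalation-valve resistance `R_V`, solved in
  closed form by eigen decomposition.

The linear model exists to supply reference time constants
(`(R+2R_V)C`, `(R+R_V)C`, `RC`), to identify the five governing ratios
(`R2/R1, C2/C1, R_V/R1, DP2/DP1, PEEP2/PEEP1`), and to cross-validate the
simulator in the limit where their assumptions coincide.

## Network topology and states

Both pressure sources carry the same composite periodic waveform; the
check valves, not any explicit switching, decide which source is active in
each phase. Four capacitive nodes (inspiratory split, expiratory merge,
two patient airway openings) hold the tube-wall storage, aggregated from
the half-compliances of their adjacent segments (1 mL/cmH2O per metre of
tube by default). The state vector is six volumes: four node storages and
two lung volumes. Branch flows are recovered at every evaluation by
inverting each branch's strictly monotone series pressure-drop law
(bracketed secant, warm-started, tolerance 1e-9 relative); lung flows are
closed-form for constant laws. The right-hand side is compiled with numba;
the pure-Python element laws in `components.py` are the reference
semantics and the test suite pins the two together.

A 15 cm × 4 mm short-circuit tube bridges the split and merge nodes. It
reproduces the bypass that keeps real ventilator controllers stable and,
during inspiration, pressurises the expiratory side so patients cannot
exhale against the inspiratory phase.

## Element laws and defaults

| Parameter | Default | Why |
|---|---|---|
| Tube limbs | L = 1 m, D = 20 mm, ε = 0.2 mm | standard breathing-circuit hose |
| Tube wall compliance | 1 mL/cmH2O per m | typical flextube value; the authoritative quantity (the pressure–diameter coefficient is derived from it, not vice versa) |
| One-way valve K | 9.01e-4 cmH2O/(L/min)² | bench-characterised coefficients of the splitter hardware |
| Filter K | 4.80e-4 cmH2O/(L/min)² | idem; placed on each patient's *expiratory* limb (the cross-contamination barrier position) |
| In-line PEEP valve K | 1.24e-3 cmH2O/(L/min)² | idem; always present on patient 2's expiratory branch, even at zero threshold |
| Exhalation valve | `ΔP = R_V q̇`, R_V = 1.5 cmH2O/(L/s) | linearisation of the ventilator's servo valve; the calibration module estimates R_V from pressure traces |
| Gas | ρ = 1.2 kg/m³, μ = 1.81e-5 Pa·s | air at ~20 °C (not stated by the hardware tables; config-overridable) |
| Check-valve smoothing | 0.01 cmH2O | ideal diodes are nonsmooth; a C¹ quadratic ramp of this width keeps the ODE integrable without visible bias (results unchanged at 0.001) |
| Friction, Re 2000–4000 | linear blend laminar↔Haaland | the transitional regime is undefined; continuity is what the solver needs |

Loss coefficients must carry explicit unit tags in config files
(`cmH2O/(L/min)²` vendor units vs canonical `cmH2O/(L/s)²`, factor 3600):
silent unit mistakes here are a factor-3600 error.

Ventilator waveform: inspiration is an underdamped second-order step from
PEEP to P_max (damping ratio from the 5% overshoot, natural frequency
from the 0.15 s rise time), expiration a logistic fall (midpoint 0.05 s,
scale 0.02 s). These four shape parameters are matched to the visual
shape of typical pressure-controlled waveforms, not fitted to any
machine, and are config-exposed.

## Integration and periodicity

LSODA integrates each phase segment separately (the phase switch is the
stiffest moment) at rtol 1e-3 (config), atol 1e-8, ≥200 samples/cycle so
the downstream exponential fits are well conditioned. `run_to_periodic`
repeats cycles until tidal and end-expiratory volumes change by <0.1%
between cycles; with lungs initialised at their relaxed PEEP volumes this
takes 2–5 cycles (more deep in the auto-PEEP regime, where the trapped
volume accumulates over cycles). Halving rtol changes tidal volumes by
<1%.

## Exhalation metrics

The last periodic cycle's expiratory lung-volume trace is fitted with
`a + b·e^(−t/τ)` (nonlinear least squares; R² against the window mean).
Because inspiratory flow is nonzero when the machine switches phase, the
lung keeps filling for ~0.1–0.2 s while the source pressure falls; the
fit window therefore starts at the **volume peak** — the initiation of
exhalation proper, which is also where the exhalatory driving pressure
`DP_i = P_i − PEEP_i` is defined (at the peak the lung flow vanishes, so
`P_i` is the elastic recoil `V_peak/C`). The raw machine window of length
`t_ex` remains available (`from_peak=False`). When gas is trapped the
fitted asymptote `a` sits at the trapped level and is reported as such.

`τ* = 4τ/t_ex` with `t_ex = 60/BR − t_ins`; `τ* > 1` flags auto-PEEP.
This single-τ criterion is deliberately simple — and, we find,
*conservative* for nonlinear circuits: the fitted τ is dominated by the
slow, quadratic-loss-limited early decay, while the low-flow tail empties
much faster than `e^(−t/τ)` suggests. Identical patients at driving
pressure ratio 1.5 illustrate it: τ*₂ ≈ 1.02–1.03, yet the measured
trapped volume is ~1.6 mL (≈0.2% of the tidal volume). Flagged rows
should be read together with the end-expiratory volumes the sweep also
records.

## Valve tuning (the numerical operator)

On the bench the driving pressures and PEEPs are set by turning knobs
while watching manometers. Numerically, `tune_pinch_valves` runs a
bracketed secant on each pinch coefficient (DP is monotone decreasing in
K), re-simulating to loose periodicity per iterate and warm-starting
states; convergence is DP within 0.1 cmH2O. `tune_peep_threshold` is
closed-form (threshold = target − ventilator PEEP, the valve stacks on
the machine PEEP) plus a verification run. Targets above what the
ventilator plateau can deliver raise an error carrying the maximum
achievable DP; sweep rows hit by it are flagged `untunable` and simulated
fully open instead of being dropped — the high-DP/high-PEEP corner of the
study grid (DP₂ = 22.5 cmH2O on PEEP₂ = 10 cmH2O needs 32.5 cmH2O, above
the 32 cmH2O plateau) is physically out of reach for this hardware.

## Parametric study

Anchors: patient 1 fixed at R₁ = 5 cmH2O/(L/s), C₁ = 35 mL/cmH2O,
DP₁ = 15 cmH2O. Grids: R₂ ∈ [2, 8], C₂ ∈ [27.5, 42.5] mL/cmH2O (default
3×3; resolution config-exposed), DP₂/DP₁ ∈ {0.75, 1, 1.5},
PEEP₂/PEEP₁ ∈ {1, 1.5, 2}. Per point: set threshold, tune pinches, run to
periodic steady state, fit both expirations, record τ*, auto-PEEP flags,
R², end-expiratory volumes and the asymmetry coefficients
`τ*/τ*_ref − 1` against the equal-DP rows. Tuning warm starts only affect
iteration counts, so execution order cannot change results. The auto-PEEP
boundary is the linearly interpolated τ* = 1 level set over the
(R₂/R₁, C₂/C₁) grid.

## Calibration

Loss coefficients: no-intercept least squares of `ΔP = K q²`
(closed form `K = Σq²ΔP / Σq⁴`). Exhalation-valve resistance: R_V is the
argmin of a functional summing, over three probe pressures (each airway
and the expiratory limb), the time-averaged squared relative error
between measured and simulated traces; samples with measured pressure
below 0.5 cmH2O are excluded (relative errors blow up near zero
crossings). The optimiser is a grid scan plus golden-section refinement —
each evaluation is a full simulation, so derivative-free is the robust
choice; an edge minimum is flagged, not refined. Multiple experiments
(e.g. three driving pressures) can be pooled into one functional
(default) or minimised separately.

## Synthetic bench data

No real bench traces ship with the package. The pseudo-experiment
generator runs the simulator at a known R_V, samples the three probe
pressures at 100 Hz and applies seeded multiplicative Gaussian noise —
emulating the sensor chain's relative error. It reproduces neither sensor
drift, quantisation, trigger jitter, nor any model-structure mismatch
between the simulator and a real circuit; recovery tests on it therefore
demonstrate identifiability of R_V under noise, not hardware-level
accuracy. All stochastic outputs are deterministic given (config, seed).

## Numerical problem sizes

Defaults keep every standard computation interactive: one tuned periodic
point ≈ 0.2–0.5 s, the full 81-point study ≈ 20 s, the 20-scenario
R_V-recovery experiment ≈ 30 s (single CPU). Sweep resolution, cycle
budgets and tolerances are all config parameters.

## Known limitations

* Constant (or merely tabulated) lung laws: no tissue viscoelasticity, no
  volume-history dependence, no spontaneous effort (patients are assumed
  paralysed).
* The exhalation valve is a fixed linear resistance; real servo valves
  change opening within a cycle and differ between ventilator models.
* No gas compressibility, inertance, temperature or humidity effects; the
  circuit inventory (one threshold valve, on patient 2) is fixed.
* No ventilator controller feedback: the source waveform is prescribed,
  so controller-circuit interactions (alarms, flow compensation) are out
  of scope.
* The auto-PEEP flag is the 4τ/t_ex ratio of a single-exponential fit;
  see above for why it can over-call marginal cases.
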