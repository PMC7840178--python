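# Methods

## Model

### Cell electrophysiology

Each node carries the 40-variable adult mouse ventricular cardiomyocyte
model of Bondarenko and co-workers (apex parameter set): Markov chains for
the fast Na⁺ channel (9 states), the L-type Ca²⁺ channel (8 states) and the
rapid delayed rectifier (5 states), Hodgkin–Huxley gates for the remaining
K⁺ currents, a four-compartment Ca²⁺ handling system (myoplasm, dyadic
subspace, junctional and network SR with RyR release), and dynamic Na⁺/K⁺
bookkeeping. Fifteen sarcolemmal currents sum to the total ionic current;
the membrane voltage obeys

    dV/dt = −(Iion + IChR2 − Istim)/Cm.

The parameter set is transcribed in `optodrift/ionic.py` with one constant
per named field of `IonicParams`; the resting state of the transcription is
a genuine fixed point (residual |dV/dt| ≈ 10⁻¹² mV/ms at −82.42 mV) and the
current balance at rest closes to <10⁻³ pA/pF.

Two tagged kinetic adjustments to the published Na⁺ chain are part of the
model variant (`bondarenko2004-apex+fast-recovery`) and were calibrated
once against the tissue-level reference numbers (see *Calibration*):

* `na_recovery_scale = 3.0` multiplies both directions of the
  closed ↔ closed-inactivated exchange (α_Na3, β_Na3). This accelerates
  recovery from inactivation (the published chain recovers with τ ≈ 100 ms
  at diastolic voltages, which pins the spiral period near 95 ms) while
  leaving the steady-state availability curve and the detailed-balance
  open-re-entry rate b_Na2 — hence the small plateau window current —
  exactly as published.
* `na_avail_shift_mv = 4.0` moves the steady-state availability midpoint
  4 mV toward negative potentials (a factor e^(4/7.7) on β_Na3). This
  steepens the loss of Na⁺ availability per mV of resting depolarization,
  which is what lets a few mV of light-induced depolarization slow
  conduction measurably instead of being cancelled by the concomitant
  threshold-proximity speed-up.

A property of the published Markov Na⁺ chain worth knowing: the model
sustains a quasi-stable depolarized equilibrium near −34 mV, carried by a
persistent window current. Trajectories that repolarize too slowly (for
example under a too-coarse integrator) are captured by it. The availability
shift above deepens diastolic inactivation and shrinks this window current;
the integrator defaults below keep single cells and tissue on the
physiological branch.

### ChR2 photocurrent

Light sensitivity uses the four-state ChR2(H134R) photocycle (two closed,
two open states) with photon-absorption rates proportional to irradiance
(retinal cross-section 1.2·10⁻⁸ µm², wavelength 470 nm, loss factor 1.3),
voltage-dependent open-state closure Gd1(V) and recovery Gr(V), and
log-saturating inter-open-state transitions. The photocurrent is

    IChR2 = g_ChR2 · G(V) · (O1 + γ O2) · (V − E_ChR2),

with the empirical rectification G(V), γ = 0.1 and E_ChR2 = 0. The
sigmoidal light-activation function of the source model is evaluated at its
algebraic steady state: its ~1 ms relaxation is far below every protocol
timescale here (illumination changes every ≥50 ms). Consequence: the
photocycle stays exactly four-dimensional per node.

`g_ChR2` (expression level) is the one constant the photocycle literature
does not fix; see *Calibration*.

### Tissue

2D monodomain on a cell-centered grid, dx = 0.025 cm, isotropic
D = 0.00157 cm²/ms, no-flux boundaries implemented as ghosts mirrored
across the boundary face (the conservative form: a reaction-free diffusion
step preserves ΣV to round-off). Strip protocols use 100×10 nodes
(2.5 × 0.25 cm), spiral protocols 100×100 (2.5 × 2.5 cm).

Spirals are initialized by partitioning the square domain into quadrants
seeded with four full cell states sampled from one paced action potential —
clockwise from top-left: rest, depolarized (0.5 ms past the upstroke),
early repolarization (−30 mV falling) and late repolarization (−70 mV
falling). The depolarized quarter propagates into the resting quarter,
curls into the recovering lower half, and a single sustained rotor (exactly
one phase singularity) results after a ~200 ms transient. Independent
initial conditions for ensembles shift the quadrant intersection by seeded
offsets (≤2 mm).

## Numerics

The stiff parts of this model are the dyadic-subspace Ca²⁺ (turnover rate
V_myo/V_ss/τ_xfer ≈ 2·10³ ms⁻¹) and RyR activation (k_a⁺·Ca_ss⁴ ≈ 10⁴ ms⁻¹
at peak subspace Ca²⁺) — this is why the source model needed RK4 at
dt = 10⁻⁴ ms. The solver here takes one operator-split step per node:

1. explicit 5-point diffusion on V;
2. forward Euler for V, concentrations, buffers and P_RyR;
3. exact exponential relaxation for subspace Ca²⁺ (coefficients frozen over
   the step);
4. Rush–Larsen exponential updates for the eight HH gates (tabulated
   steady states and decay factors);
5. diagonally-implicit updates x ← (x + dt·A)/(1 + dt·B) for every Markov
   occupancy — unconditionally stable and positivity-preserving — with a
   Gauss–Seidel ordering plus renormalization for the RyR chain (whose
   stiff rate sits in the influx term) and renormalization of the ChR2
   occupancies (conservation to <10⁻⁹ per step).

All voltage-dependent rates are linearly interpolated from a 0.02 mV
lookup table shared between the compiled kernel and the reference
right-hand side; reversal potentials and the Na⁺-pump saturation are
refreshed every 0.25 ms. The kernel is a single numba-compiled loop
(~10⁷ node-steps/s on one core).

Accuracy: the scheme is first order; against an adaptive stiff reference
(LSODA, rtol 10⁻⁹) a paced action potential at dt = 0.0025 ms is accurate
to ~2 mV in the steep repolarization phase and ~0.03 mV at 50 ms, halving
with dt. Defaults: dt = 0.0025 ms for conduction-velocity work (at
dt ≥ 0.004 ms the wake repolarizes so slowly that illuminated strips show
a spurious CV increase), dt = 0.003 ms for spiral protocols (the dark/lit
frequency ratio is insensitive at this step). Explicit RK4 on the full
right-hand side is kept as `method="rk4"` and is stable only below
~3·10⁻⁴ ms.

Other conventions: activation time = −20 mV upstroke crossing with linear
sub-sample interpolation, CV averaged over the last three captured beats;
dominant frequency = argmax above 1 Hz of a mean-removed, Hann-tapered,
8×-zero-padded periodogram; spatial derivatives by central differences;
tip = intersection of the V = −40 mV isolines of two consecutive frames
(marching squares + exact segment intersection, topological charge from
the isoline-gradient orientation); curvature and speed from 7-sample
Savitzky–Golay derivatives; core center/diameter per rotation = mean tip
position and minimal enclosing circle (Welzl) of one cycle; drift speed on
per-rotation centers so rotation is separated from translation; the
exponential drift fit V(t) = V0·e^(−t/τ) uses the protocol clock (t = 0 at
light onset) with positivity bounds and a τ-cap flag for non-decaying
data; termination = tip absence ≥ 50 ms together with active area (V >
−40 mV) below 5% of the domain.

## Calibration

Four constants are not recoverable from the source literature and were
fixed once, jointly, against the tissue-level reference numbers
(plane-wave CV 43.9 cm/s; dark spiral ~15.3 Hz; ~5% CV slowing and ~26%
rotation-frequency reduction under uniform 0.02 mW/mm², which also pins
0.02 mW/mm² as sub-threshold):

| constant | value | set by |
|---|---|---|
| D | 0.00157 cm²/ms | dark CV (the printed diffusivity is dimensionally inconsistent and an order of magnitude away from any value consistent with the printed CV) |
| `na_recovery_scale` | 3.0 | dark spiral frequency |
| `na_avail_shift_mv` | 4.0 | sign/size of the light-induced CV slowing |
| `g_ChR2` | 2.9 mS/cm² | size of the light effects within the sub-threshold window |

With these defaults the measured values are CV 43.8 cm/s, dark DF 16.1 Hz,
CV slowing 5.8%, DF reduction ~21–22%, and the single-cell excitation
threshold sits above 0.02 mW/mm². The calibration is recorded here once
and not revisited per protocol.

## Problem sizes

Reported runs use the native grids (100×10 strips, 100×100 spirals).
Durations are the package's standard working scale: 4 beats at 5 Hz for
CV; 200 ms spiral settling followed by 650 ms (dark) / 800 ms (lit)
branches with 600 ms spectral windows; 500–600 ms gradient-drift runs for
mechanism checks. The `experiments` module's `paper` preset runs the full
2 s protocols with the N = 10 seeded initial-condition ensemble for the
displacement/termination/MSD tables; these are multi-hour runs on one
core and are not exercised by the test suite.

## Synthetic fixtures

`optodrift.fixtures` generates every input structure the analysis stages
assume — circular/cycloidal/exponentially-decaying-drift tip trajectories,
translating plane-wave and rotating-phase voltage movies, and quiescent
ramp/logistic voltage profiles — each with closed-form ground truth and
seeded, bit-reproducible noise, written into the same containers as solver
output. They emulate the geometric and statistical structure of solver
products, not ionic dynamics: fixture-based tests validate the
measurement pipeline (CV, DF, curvature, drift fits, MSD), while
statements about the tissue model itself rest on the solver-based tests.

## Known limitations

* The variant adjustments above are a calibration to tissue-level
  observables, not a re-derivation of the (unidentified) "improved" Na⁺
  kinetics of the source model; single-cell restitution details inherited
  from them are untested.
* The DF reduction under global light rises toward its asymptote over
  ~1 s of illumination; shorter windows read 1–3 points lower than the
  2 s value.
* The scheme is first order in dt; quantities tied to wake repolarization
  (lit CV, spiral period) need dt ≤ 0.003 ms.
* No anisotropy, bidomain effects, mechanics, 3D geometry or photon
  transport (the exponential transmural light profile is imposed, space
  constant 0.6 mm).
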