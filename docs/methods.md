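# Methods

## The model family

`ca3deg` builds multicompartmental, conductance-based models of
hippocampal CA3 pyramidal neurons and studies how heterogeneous ion-channel
combinations produce the cell type's signature electrophysiology —
including complex spike bursts (CSB) — via unbiased stochastic search.

Each model is a branched cable of iso-potential compartments. The membrane
of every compartment carries a passive leak and up to ten active
conductances with Hodgkin–Huxley gating: fast sodium (NaF),
delayed-rectifier, A-type and M-type potassium (KDR, KA, KM), L/N/T-type
calcium (CaL, CaN, CaT), small- and big-conductance calcium-activated
potassium (SK, BK), and HCN. Sodium/potassium currents are Ohmic
(E_Na = +50 mV, E_K = −91 mV); calcium-channel and glutamate-receptor
currents use the Goldman–Hodgkin–Katz (GHK) constant-field equation.
Intracellular calcium is tracked per compartment in four concentric
shells with a mobile buffer, a rest-balanced membrane pump, and radial plus
longitudinal diffusion. Simulations run at a nominal 34 °C; the fixed
integration step is 25 µs.

Fourteen parameters span the search space: R_m (60–100 kΩ·cm²), R_a
(150–400 Ω·cm), ten maximal conductance/permeability scales
(ḡ_Na 7.5–30, ḡ_KDR 5.5–22, ḡ_KA 0.05–0.2, ḡ_CaL 1.25–5, ḡ_CaT 0.125–0.5,
ḡ_CaN 1.25–5, ḡ_KM 0.005–0.02, ḡ_BK 0.4–1.6, ḡ_SK 0.25–1 mS/cm²,
ḡ_h 0.5–6 µS/cm²) and the calcium pump/buffer totals (totpp 0.01–0.5,
totbuf 0.1–2.5). Sampling is independent and uniform per parameter; a
model is *valid* when all 11 intrinsic measurements fall inside their
electrophysiological bounds (inclusive).

## Morphology

The reference workflow runs on a reduced synthetic morphology rather than
a full reconstruction: a spherical soma (25 µm), a 500 µm apical trunk
tapering from 10 to 5 µm that continues into a flaring 300 µm "tuft"
equivalent cylinder (8 → 28 µm), two thick oblique branches attached near
the 150 and 300 µm recording sites, and two basal equivalent cylinders.
Total membrane area is ≈ 78,000 µm², chosen so that with R_m = 60 kΩ·cm²
the somatic input resistance lands in the physiological 60–150 MΩ band.

The taper-plus-flare shape is an area-equivalent representation of the
profuse distal branching of real CA3 apical arbors: a back-propagating AP
running into a continuously growing impedance load attenuates, which a
uniform active cylinder does not. The oblique branch points add the
localized loading that real arbors provide at every bifurcation. Full SWC
reconstructions load through the same pipeline (`morphology.load_swc`).

Discretization follows the d_λ rule: each section receives the smallest
odd number of equal segments such that none exceeds `d_lambda` (default
0.1) times the AC length constant at `f_lambda` (default 100 Hz).
Compartment counts are decided once on the base passive constants; a
sampled model's own R_a rescales the axial coupling conductances without
re-gridding, so every model in a population shares the same compartment
layout and rows remain directly comparable.

## Channel kinetics and distributions

Gating kinetics are *data*: every channel is declared in a YAML kinetics
file as Boltzmann steady states with constant or bell-shaped (Gaussian in
voltage) time constants; SK activation is a Hill function of
outer-shell calcium (kd 0.35 µM, n 5), and BK is a voltage Boltzmann whose
half-activation shifts leftward with log10 of calcium. The packaged
defaults are a CA3/CA1-style parameterization tuned so that the *base*
parameter vector satisfies all 11 validation bounds on the synthetic
morphology; they are the package's defaults, not measurements, and can be
replaced wholesale by pointing a run at another kinetics file.

Distributions over the arbor (path distance x from the soma): NaF, KDR,
CaT, CaN, SK, BK uniform; CaL perisomatic (x ≤ 50 µm); KM perisomatic
(x ≤ 100 µm); KA with proximal kinetics at x ≤ 100 µm and distal kinetics
beyond, density rising as (1 + 3x/100) along the apical dendrite; HCN with
the apical gradient g_h(x) = ḡ_h(1 + 3x/100) and ḡ_h elsewhere.
Calcium-channel "conductance" search values (mS/cm²) convert to GHK
permeabilities through the kinetics constant `ca_perm_per_mS`
(4.06 × 10⁻⁴ cm/s per mS/cm²), sized so a single somatic AP raises
outer-shell calcium by a few hundred nanomolar.

## Numerics

The voltage system advances by backward Euler. At each step the ionic
currents are linearized about the present voltage (Ohmic terms exactly;
GHK terms through the tabulated flux factors A(v), B(v) with
i = P·(A·c_in − B·c_out) and their local slopes), and the resulting
symmetric branched tridiagonal system is solved directly on the
Hines-ordered compartment tree in one up/down sweep — unconditionally
stable at any step size. Gates advance by exponential Euler against
voltage lookup tables (0.05 mV grid), which keeps them in [0, 1] for any
dt. Calcium uses operator splitting: membrane influx is accumulated every
step, while diffusion, buffering and pump extrusion update on a substep
of up to 4 × 25 µs = 100 µs, bounded by the explicit radial-diffusion
stability limit of the thinnest shell present. Buffer binding and pump
extrusion are solved implicitly in closed form (per-shell quadratics),
which conserves mass exactly and is the reason the pump is balanced to be
a fixed point at the 100 nM resting concentration. Everything is float64
with a fixed operation order, so repeated runs are bit-identical.

Synaptic AMPAR/NMDAR input enters as GHK point currents (Na, K and — for
NMDAR — Ca with relative permeability 10.6) gated by peak-normalized
double-exponential kernels (AMPA 2/10 ms, NMDA 5/50 ms) and the
magnesium block MgB(v) = 1/(1 + ([Mg]ₒ/3.57)·e^(−0.062v)). Synchronous
presynaptic events increment two exponential state variables per
receptor, so arbitrarily many events superpose linearly at O(1) cost.
Note that the printed ionic composition puts the multi-ion GHK reversal
at −2.3 mV for AMPAR but +4.1 mV for NMDAR; the conventional "0 mV"
description is approximate (the calcium term is inward far above 0 mV).

## Measurements

The 11 validation measurements follow the standard protocols: V_RMP/V_SD
from the 5–6 s quiescent window; R_in as the V–I slope of −50…+50 pA,
300 ms steps (steady state = mean of the last 10 %); sag ratio from the
−250 pA × 800 ms response; impedance profile from a 100 pA peak-to-peak
chirp sweeping 0→15 Hz in 15 s; f_250 as the spike count during a
250 pA × 1 s step; and bAP amplitudes (first-AP peak minus local
baseline) at the soma and ~150/~300 µm apical sites after 1 nA × 50 ms.
The further AP measurements (latency, first ISI, AHP, half-width,
threshold at the 20 V/s crossing, dV/dt extremes per site) come from the
same recordings.

Estimator choices worth knowing:

* Spikes are upward crossings of −20 mV whose peak reaches 0 mV, with
  1 ms refractory separation — deliberately tolerant of the large
  within-burst amplitude decrements of CSB.
* The impedance profile |Z(f)| = |FFT(v)/FFT(i)| is evaluated on
  [0.5, 15] Hz (0.5 Hz is also the Q_R reference). The record gets an
  end-only 5 % cosine taper: the response starts smoothly at rest, but an
  abrupt stop at the top of the sweep leaks into the lowest bins, and a
  *leading* taper would distort the slow early cycles that carry all the
  low-frequency energy. The scalar estimates (f_R, Q_R, |Z|_max)
  additionally use a 5-bin moving average, because the argmax of a
  weakly resonant (Q ≤ 1.1) profile is otherwise decided by per-bin FFT
  ripple. Both choices were validated against closed-form RC and
  band-pass oracles and against steady single-sine probes of the full
  model.
* V_ramp (CSB) is the peak of a 0.5 s-window running median (on a 1 kHz
  decimated copy, reflect padding) minus V_RMP.

## Phenotypes, CSB and knockouts

A model is intrinsically bursting (IB) if its 240 pA × 5.5 s somatic
response contains three consecutive spikes spanning ≤ 25 ms whose first
amplitude exceeds the second by more than 5 mV (the threshold separates
genuine burst decrement, typically ~10 mV, from jitter); otherwise it is
regular spiking (RS). A CSB pulse is valid when three criteria hold
simultaneously: ≥ 3 APs within a sliding 25 ms window inside the pulse,
ΔV_AP = V_AP1 − V_AP2 ∈ [10, 30] mV, and V_ramp ∈ [10, 30] mV (all
inclusive). The CSB rate is the valid fraction of pulses 2–5 — the first
pulse bursts in essentially every model and is excluded. Five induction
protocols are built in: 5 somatic pulses at 600/900/1200 pA (100 ms on,
80 ms off), 5 dendritic pulses at 1000 pA into the ~150 µm site (50/50 ms),
and 5 synchronous presynaptic volleys at 5 Hz into 100 stratum-radiatum
synapses.

Virtual knockouts zero exactly one maximal conductance (or the NMDAR
permeability, with AMPAR intact) and re-run the protocol with identical
seeds and synapse placement; NaF and KDR are excluded so every knockout
still spikes. Effects are percentage changes of ΔV_AP, V_ramp and CSB
rate against the intact base run (undefined when the base quantity is 0).
Group statistics use the Wilcoxon rank-sum test for the unpaired IB vs RS
comparisons and the one-sample signed-rank test against zero for
knockout effects.

## Synthetic data

The `synthetic_data` generators exist so that every trace-analysis
operator can be tested against known ground truth without running the
solver: spike templates with triangular flanks (analytic half-width and
threshold), burst patterns, raised-cosine ramp plateaus, and seeded noise;
multivariate-normal population tables realizing requested correlation
structures; and closed-form RC fixtures for the resistance/impedance
oracles. They emulate the *geometry* of real recordings (amplitudes,
time courses, event counts), not their biophysics: passing these tests
shows the measurement pipeline is correct, not that the neuron model is.

## Problem sizes and reproducibility

Desk-scale runs use the reduced morphology (≈ 27 compartments) at the
full 25 µs step: the complete validation battery of one model simulates
~26 s of activity in ~4 s of wall time, and the reference scaled search
(n = 200) completes in ~15 minutes on one core. Population rows are
independent tasks seeded per (global seed, row index), so tables are
reproducible end-to-end, any row can be re-simulated bit-for-bit from its
stored parameters, and the per-row seeds would allow embarrassingly
parallel execution on larger machines. A cluster-scale search (the tens
of thousands of models a full degeneracy study uses) is the same code
with a larger `n_models`.

## Known limitations

* Gating kinetics are plausible defaults tuned to the validation bounds
  on a reduced morphology, not fits to voltage-clamp data; absolute
  yields (valid fractions, IB/RS ratios, CSB counts) therefore depend on
  them and are not comparable across kinetics files. In particular, with
  the shipped defaults the strong-drive CSB protocols mostly produce
  single spikes riding the depolarizing envelope or slow tonic trains
  rather than 3-spikes-in-25-ms bursts, so population CSB rates are low;
  the CSB scoring and knockout machinery is validated against
  constructed burst fixtures with known ground truth.
* The synthetic morphology collapses the dendritic arbor into a few
  equivalent cylinders; spatial phenomena finer than its compartment
  size (oblique-specific spikes, branch-point failure statistics) are out
  of reach.
* No axon: spike initiation is somatic.
* Calcium handling omits intracellular stores (ER, IP3/ryanodine).
* Synapses are deterministic and plasticity-free; presynaptic volleys
  are perfectly synchronous.
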