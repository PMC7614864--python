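# ca3deg

Heterogeneous populations of conductance-based CA3 pyramidal-neuron
models: stochastic parameter search, signature electrophysiology,
complex spike bursts, and virtual knockouts.

## What this package is for

Hippocampal CA3 pyramidal neurons fire characteristic **complex spike
bursts** (CSB) — several action potentials packed into ~25 ms riding a
depolarizing ramp, with decrementing spike amplitude — and they do so
despite large cell-to-cell variability in their ion-channel composition.
`ca3deg` is a desk-scale laboratory for studying that *ion-channel
degeneracy*: instead of one hand-tuned neuron model, it generates
populations of multicompartmental Hodgkin–Huxley models by sampling 14
biophysical parameters (passive constants, ten channel densities, two
calcium-handling totals) uniformly within physiological ranges, keeps the
models whose 11 intrinsic measurements

> V_RMP, V_SD, R_in, sag ratio, resonance frequency f_R, resonance
> strength Q_R, |Z|_max, firing rate f_250, and bAP amplitudes at the
> soma / 150 µm / 300 µm

fall within electrophysiological bounds (MPMOSS — multi-parametric
multi-objective stochastic search, i.e. rejection sampling), classifies
the survivors into intrinsically-bursting (IB) vs regular-spiking (RS)
phenotypes, elicits CSB through five somatic/dendritic/synaptic
protocols, and quantifies each channel's contribution by virtual
knockout (re-simulation with exactly one conductance zeroed).

Everything runs on a built-in reduced CA3-like morphology with an own
implicit branched-cable solver (25 µs step; Hines-ordered direct solve;
GHK calcium and AMPAR/NMDAR synapse currents; four-shell calcium handling
with buffer, pump and diffusion). See `docs/methods.md` for the model,
numerics and estimator details.

## Worked example

```python
import numpy as np
from ca3deg import build_synthetic_morphology, discretize, ParameterVector
from ca3deg.mpmoss import measure_model, validate, run_search

model = build_synthetic_morphology()          # reduced CA3-like arbor
cable = discretize(model)                     # d_lambda rule, ~27 compartments

base = ParameterVector()                      # the base parameter set
m = measure_model(cable, base)                # full validation battery (~4 s)
ok, flags = validate(m)
print(f"valid={ok}  RMP={m.v_rmp:.1f} mV  R_in={m.r_in:.1f} MOhm  "
      f"sag={m.sag:.3f}  f_R={m.f_r:.2f} Hz  f_250={m.f_250:.0f} Hz")
print(f"bAP amplitudes: {m.v_ap0:.1f} / {m.v_ap150:.1f} / {m.v_ap300:.1f} mV")
```

prints (exact numbers from the shipped defaults):

```
valid=True  RMP=-66.7 mV  R_in=66.2 MOhm  sag=0.949  f_R=1.20 Hz  f_250=7 Hz
bAP amplitudes: 90.9 / 87.5 / 79.7 mV
```

i.e. the base model rests near −67 mV with a 66 MΩ input resistance, a
weak sag and a ~1 Hz impedance resonance, fires 7 spikes during a 250 pA
second, and its backpropagating AP attenuates from ~91 mV at the soma to
~80 mV at the 300 µm apical site — all inside the CA3 validation bounds.

A small population search, phenotype labels and CSB scoring:

```python
table = run_search(cable, 50, seed=1)         # 50 random models
print(table["valid"].sum(), "valid of", len(table))
```

The same stages are scriptable from the shell:

```bash
ca3deg search   --n 200 --seed 1 --out run/
ca3deg classify --out run/
ca3deg csb      --out run/ --protocol somatic900 --protocol synaptic5Hz
ca3deg vkm      --out run/
ca3deg report   --out run/
```

Each stage persists a CSV artifact plus a provenance sidecar (config
digest + seed) under `run/`, and re-running with an unchanged
configuration reuses the stored artifact byte-for-byte.

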