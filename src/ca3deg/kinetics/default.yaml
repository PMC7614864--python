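# Default channel gating kinetics -- CA3/CA1 pyramidal-neuron style HH
# parameterizations in declarative Boltzmann / Gaussian-tau form.
#
# These are the package defaults, written for this model family (they are
# a documented parameterization, not measurements): steady states are
# Boltzmann functions of voltage (k > 0 activation, k < 0 inactivation),
# time constants are constant or Gaussian-bell shaped in voltage (ms).
# Calcium-gate steady states are Hill functions of submembrane calcium
# (mM). BK uses a voltage Boltzmann whose half-activation shifts by
# `shift_per_decade` mV per decade of calcium above `ca_ref` (mM).
#
# `ca_perm_per_mS` converts the conductance-style calcium-channel search
# parameter (mS/cm^2) into a GHK permeability (cm/s).
ca_perm_per_mS: 0.00040552255147334736
channels:
  BK:
    gates:
    - depends: v_ca_shift
      inf:
        ca_ref: 0.0003
        k: 10.0
        kind: boltzmann
        shift_per_decade: 45.0
        vhalf: -5.0
      name: o
      power: 1
      tau:
        kind: const
        value: 1.5
    ion: k
    law: ohmic
    reversal: e_k
  CaL:
    gates:
    - depends: v
      inf:
        k: 6.0
        kind: boltzmann
        vhalf: -5.0
      name: m
      power: 2
      tau:
        amp: 1.0
        base: 0.5
        kind: gauss
        sigma: 15.0
        vhalf: -12.0
    ion: ca
    law: ghk
    valence: 2
  CaN:
    gates:
    - depends: v
      inf:
        k: 7.0
        kind: boltzmann
        vhalf: -14.0
      name: m
      power: 2
      tau:
        amp: 1.0
        base: 0.5
        kind: gauss
        sigma: 15.0
        vhalf: -14.0
    - depends: v
      inf:
        k: -10.0
        kind: boltzmann
        vhalf: -67.0
      name: h
      power: 1
      tau:
        kind: const
        value: 70.0
    ion: ca
    law: ghk
    valence: 2
  CaT:
    gates:
    - depends: v
      inf:
        k: 6.0
        kind: boltzmann
        vhalf: -45.0
      name: m
      power: 2
      tau:
        amp: 3.0
        base: 1.5
        kind: gauss
        sigma: 15.0
        vhalf: -45.0
    - depends: v
      inf:
        k: -5.0
        kind: boltzmann
        vhalf: -78.0
      name: h
      power: 1
      tau:
        kind: const
        value: 30.0
    ion: ca
    law: ghk
    valence: 2
  HCN:
    gates:
    - depends: v
      inf:
        k: -8.879186387761468
        kind: boltzmann
        vhalf: -99.5
      name: l
      power: 1
      tau:
        kind: gauss
        base: 20.0
        amp: 170.0
        vhalf: -74.0
        sigma: 10.0
    ion: nonspecific
    law: ohmic
    reversal: e_h
  KA_dist:
    gates:
    - depends: v
      inf:
        k: 11.0
        kind: boltzmann
        vhalf: -10.0
      name: n
      power: 1
      tau:
        amp: 1.0
        base: 0.6
        kind: gauss
        sigma: 25.0
        vhalf: -40.0
    - depends: v
      inf:
        k: -6.0
        kind: boltzmann
        vhalf: -70.0
      name: l
      power: 1
      tau:
        amp: 12.0
        base: 6.0
        kind: gauss
        sigma: 25.0
        vhalf: -50.0
    ion: k
    law: ohmic
    reversal: e_k
  KA_prox:
    gates:
    - depends: v
      inf:
        k: 11.0
        kind: boltzmann
        vhalf: 0.0
      name: n
      power: 1
      tau:
        amp: 1.0
        base: 0.6
        kind: gauss
        sigma: 25.0
        vhalf: -30.0
    - depends: v
      inf:
        k: -6.0
        kind: boltzmann
        vhalf: -70.0
      name: l
      power: 1
      tau:
        amp: 12.0
        base: 6.0
        kind: gauss
        sigma: 25.0
        vhalf: -50.0
    ion: k
    law: ohmic
    reversal: e_k
  KDR:
    gates:
    - depends: v
      inf:
        k: 9.0
        kind: boltzmann
        vhalf: -5.043038907346451
      name: n
      power: 2
      tau:
        amp: 8.0
        base: 0.6
        kind: gauss
        sigma: 30.0
        vhalf: -55.0
    ion: k
    law: ohmic
    reversal: e_k
  KM:
    gates:
    - depends: v
      inf:
        k: 4.0
        kind: boltzmann
        vhalf: -62.1591742564361
      name: m
      power: 1
      tau:
        kind: const
        value: 95.0
    ion: k
    law: ohmic
    reversal: e_k
  NaF:
    gates:
    - depends: v
      inf:
        k: 5.529134307166184
        kind: boltzmann
        vhalf: -42.033141379070265
      name: m
      power: 3
      tau:
        amp: 0.1
        base: 0.05
        kind: gauss
        sigma: 15.0
        vhalf: -42.033141379070265
    - depends: v
      inf:
        k: -5.0
        kind: boltzmann
        vhalf: -64.84490204776391
      name: h
      power: 1
      tau:
        amp: 8.0
        base: 1.2110898982332046
        kind: gauss
        sigma: 18.0
        vhalf: -64.84490204776391
    ion: na
    law: ohmic
    reversal: e_na
  SK:
    gates:
    - depends: ca
      inf:
        kd: 0.0003048239042179386
        kind: hill
        n: 5
      name: q
      power: 1
      tau:
        kind: const
        value: 8.00047575188753
    ion: k
    law: ohmic
    reversal: e_k
e_h: -30.0
e_k: -91.0
e_na: 50.0
temperature_c: 34.0
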