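# v1r — conductance-based modelling of embryonic Renshaw-cell excitability

Embryonic V1 interneurons destined to become Renshaw cells (V1R) display,
at the onset of spinal-cord activity, a spectrum of firing patterns in
response to a 2 s depolarizing current pulse: **single spiking** (SS, 1–3
action potentials at pulse onset), **repetitive spiking** (RS), **plateau
potentials** (PP), and **mixed events** (ME, plateaus alternating with
spiking episodes).  This package implements a single-compartment
Hodgkin–Huxley-type model in which the entire spectrum is controlled by the
balance between the persistent sodium conductance G<sub>Nap</sub> and the
delayed-rectifier potassium conductance G<sub>Kdr</sub>, together with the
full analysis toolchain built on that model.

## The model

Membrane potential obeys

```
Cin dV/dt = Gin (Vr − V) + GNat m³h (ENa − V) + GNap mp³s (ENa − V)
          + GKdr n³ (EK − V) + GA mA∞(V) hA (EK − V) + I
```

with every gate x relaxing as `τx dx/dt = x∞(V) − x`,
`x∞ = 1/(1 + exp(−(V − Vx)/kx))` (kx > 0 for activation, < 0 for
inactivation).  The INat inactivation time constant is voltage dependent,
`τh(V) = 16.5 − 13.5·tanh((V+20)/15)` ms, falling from 30 ms to 3 ms with
depolarization.  Variants: the **basic model** (leak + INat + INap + IKdr),
an **IA variant** (A-type potassium current with instantaneous activation),
and a **slow-inactivation variant** in which INap inactivates with
τs = 2 s, turning stable plateaus into recurring (pseudo-plateau) bursting
and mixed events.  Units are {mV, ms, nS, pF, pA}; the passive time
constant Cin/Gin is 13 ms.

What the package computes:

- **Deterministic simulation** (fixed-step RK4, numba-accelerated) of the
  experimental protocols: 2 s current steps, voltage-clamp step families
  with conditioning prepulses (IKdr/IA separation), 70 mV/s voltage ramps
  (INap isolation by in-silico TTX subtraction), and pharmacology as
  parameter scalings (TTX, 4-AP Hill block of IKdr).
- **Stochastic simulation** with discrete Markov channels (10 pS unitary
  conductance) by a hybrid Gillespie scheme — exact waiting times for
  frozen rates, exact exponential voltage updates between transitions.
- **Bifurcation analysis**: Hopf points by eigenvalue bisection on the
  fixed-point branches; saddle-node (fold) bifurcations of limit cycles by
  attractor-following continuation; firing-rate curves; the two-parameter
  activity map in the GNap–GKdr plane; the quiescence/plateau bistability
  region in the I–GNap plane.
- **Phenotyping**: event detection at half-amplitude, the three firing
  descriptors (mean ½Ad, CV ½Ad, ddr), SS/RS/ME/PP classification, and
  burst-structure analysis (up/down states, slow-gate phases).
- **Population analysis**: complete-linkage hierarchical clustering of
  (log mean ½Ad, CV ½Ad, log ddr) with silhouette-based selection of the
  cluster number, and Hill fitting of 4-AP dose-response curves.
- **Synthetic data**: a 163-cell feature table with five clusters at the
  reported centroids and sizes, conductance-pair populations respecting
  the observed zonation of the GNap–GKdr plane, and noisy dose-response
  tables — so every analysis is testable without recordings.

## Worked example

```python
import numpy as np
from v1r import (table1_basic, current_step_family, phenotype_trace,
                 hopf_scan, limit_cycle_fold_scan)

p = table1_basic()                       # Gin=1 nS, Cin=13 pF, I=20 pA

# firing phenotype at three conductance pairs
for gnap, gkdr in [(0.2, 10.0), (1.2, 10.0), (1.2, 2.5)]:
    tr = current_step_family(p.with_(gnap=gnap, gkdr=gkdr), [20.0])[0]
    f = phenotype_trace(tr)
    print(f"GNap={gnap:4.1f} GKdr={gkdr:5.1f} -> {f.pattern:3s} "
          f"(n={f.n_events}, ddr={f.ddr:.3f})")

# bifurcation skeleton of the GNap sweep at GKdr = 10 nS
hopfs = hopf_scan(p, "gnap", np.linspace(0.05, 2.5, 26))
on  = limit_cycle_fold_scan(p, "gnap", (0.3, 1.2), side="onset",  interior=1.2)
off = limit_cycle_fold_scan(p, "gnap", (1.2, 3.0), side="offset", interior=1.2)
print(f"SN1={on.value:.3f}  HB1={hopfs[0].value:.3f}  "
      f"HB2={hopfs[1].value:.3f}  SN2={off.value:.3f}  (nS)")
```

prints

```
GNap= 0.2 GKdr= 10.0 -> SS  (n=1, ddr=0.006)
GNap= 1.2 GKdr= 10.0 -> RS  (n=32, ddr=0.230)
GNap= 1.2 GKdr=  2.5 -> PP  (n=3, ddr=0.974)
SN1=0.648  HB1=0.810  HB2=2.128  SN2=2.424  (nS)
```

i.e. repetitive firing exists only on the GNap window between the two
folds of limit cycles (SN1, SN2), with subcritical Hopf bifurcations (HB1,
HB2) inside it delimiting where quiescence and plateau lose stability —
the mechanism behind the SS → RS → PP progression as GNap/GKdr grows.

A command-line interface mirrors the library:

```bash
v1r simulate --gnap 1.2 --gkdr 10 --step-pa 20 --out trace.csv
v1r bifurcate --sweep gnap --lo 0.1 --hi 3.0
v1r synth features --seed 1 --out features.csv
v1r cluster features.csv
v1r fit-hill doses.csv
```

## Layout

```
src/v1r/
  params.py      parameter sets, gate specifications, presets, YAML/JSON io
  model.py       equations, steady states, fixed points, stability
  _kernels.py    numba RK4 / voltage-clamp / Gillespie kernels
  protocols.py   current- and voltage-clamp protocols, pharmacology
  stochastic.py  discrete-channel simulation
  bifurcation.py Hopf and fold location, activity maps, bistability
  phenotype.py   event detection, descriptors, SS/RS/ME/PP, bursts
  population.py  clustering, silhouette, Hill fitting
  synthetic.py   cohort generators
  cli.py         command-line interface
docs/methods.md  modelling and analysis notes
```
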