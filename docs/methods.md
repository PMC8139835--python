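# Methods

## Model

The cell is a single isopotential compartment. State is
(V, m, h, mp, s, n, hA); mA is algebraic (instantaneous activation).
Default parameters (the "basic" E12.5 preset):

| quantity | value | notes |
|---|---|---|
| Cin | 13 pF (18 pF in the E14.5 preset) | median measured capacitance |
| Gin | 1 nS | leak; Cin/Gin = 13 ms |
| Vr | −60 mV | baseline imposed in current clamp |
| ENa / EK | 60 / −96 mV | |
| GNat | 20 nS | transient Na⁺ |
| GNap, GKdr | free | the two axes of the analysis |
| m (INat act.) | V½ −26 mV, k 9.5 mV, τ 1.5 ms, exponent 3 | +10 mV of mp |
| h (INat inact.) | V½ −45 mV, k −5 mV, τh(V) | τh = 16.5 − 13.5·tanh((V+20)/15) ms |
| mp (INap act.) | V½ −36 mV, k 9.5 mV, τ 1.5 ms, exponent 3 | |
| s (INap slow inact.) | V½ −30 mV, k −5 mV, τs 2 s | only in the slow-inactivation variant |
| n (IKdr act.) | V½ −20 mV, k 15 mV, τ 10 ms, exponent 3 | |
| mA / hA (IA) | −30/12 (instant); −70/−7, τ 23 ms | GA = GKdr when IA is included |

Unit system {mV, ms, nS, pF, pA}, so pF·mV/ms = pA identically.  The
A-current activation steepness is taken as +12 mV (an activation curve must
increase with V); the slow-inactivation time constant defaults to 2 s and
is exposed (`tau_s`) because shortening it illustrates how the up/down
asymmetry of bursting depends on the slow time scale.

## Numerics

**Deterministic integration** is fixed-step RK4 with dt = 0.01 ms
(kernels numba-compiled).  The fastest gate time constant is 1.5 ms and the
effective membrane time constant during a spike stays above ~0.3 ms, so
dt = 0.01 ms is two orders below the stability limit; step-halving changes
a 2 s spiking trace by <10⁻³ mV and the channel-blocked step response
matches the closed-form RC curve to <10⁻⁶ mV.  Initial conditions come from
a 2 s settling run at the holding current so the same code path serves the
slow-inactivation variant.  Divergence (non-finite state) raises with a
diagnostic instead of returning garbage.

**Fixed points** are roots of the scalar steady-state current balance F(V)
(gates eliminated at x∞; the slow gate treated as a frozen parameter),
bracketed on a 2001-point grid over [−100, 40] mV and bisected to 10⁻⁶ mV —
this finds all one or three roots of the S-shaped curve.  Stability comes
from eigenvalues of a central-finite-difference Jacobian (step 10⁻⁶)
restricted to the dynamically active variables (V, m, h, mp, n; + hA with
IA); |Re λ| < 10⁻⁹ is reported as marginal.

**Hopf points**: the chosen branch (lowest- or highest-voltage root) is
tracked along the sweep; each sign change of the real part of the leading
complex-conjugate eigenvalue pair is bisected to 10⁻³ nS (10⁻² pA).

**Folds of limit cycles** are located by attractor-following continuation:
march from a parameter value with a converged cycle toward the boundary,
inheriting the end state of the previous run; at each trial discard a 2 s
transient and declare a sustained oscillation when the peak-to-trough span
exceeds 20 mV on both halves of a 1 s window.  Because a slowly decaying
transient near the fold can masquerade as a cycle, a positive call must
survive a second transient+window round before it counts.  The boundary is
then bisected to 10⁻³ nS, always restarting from the inside (converged-
cycle) state, so the test probes existence of the cycle attractor rather
than its basin.  The 20 mV criterion separates full spiking from
subthreshold ringing near the subcritical Hopf points; it is exposed in
`bifurcation.OSC_SPAN_MV`.  Unstable cycle branches are out of numerical
scope; the bistable windows are still identified through the two stable
attractors.

**Firing rates** use 10 s runs (2 s transient discarded), rate =
1000/mean ISI from spike peaks (prominence 20 mV).  The rates "just inside"
the folds are evaluated 0.005 nS inside the located fold, continuing from
the fold's cycle state — close enough that the rate differs from its value
at the fold by well under the ±1 Hz comparison band, far enough to be
robustly on the cycle.

**Activity map**: each (GNap, GKdr) cell is labelled by an attractor census
— simulations from three canonical initial conditions (rest, depolarized,
perturbed rest) plus the stable-fixed-point census, giving SS, RS, PP or a
declared bistable combination.  Fixed points above −35 mV count as
plateaus; this threshold sits between the subthreshold depolarized states
the model produces (≤ −35 mV) and its genuine plateaus (≥ −30 mV).

**Bistability region** (I–GNap plane): for each GNap the injected-current
window with two coexisting stable fixed points is found on a 161-point I
grid and bisected to 10⁻³ pA; the minimal GNap admitting coexistence is
bisected likewise.  Note the window width shrinks linearly (~0.23 pA per
0.01 nS) toward the minimum, so a coarse I grid biases the minimum upward;
the converged value for GKdr = 5 nS is ≈1.31–1.32 nS, slightly below the
commonly quoted 1.35.

## Stochastic scheme

Maximal conductances map to channel counts N = round(G/γ), γ = 10 pS.
INat channels occupy a 4×2 chain (0–3 open m-subunits × h), INap a 4×2
chain (mp × s; without slow inactivation all channels sit in the s-open
column), IKdr a 4-state chain; a channel conducts γ iff all three
activation subunits and the inactivation gate are open.  Subunit rates are
α = x∞(V)/τx, β = (1 − x∞(V))/τx.  The hybrid simulation freezes rates at
the current voltage, draws the exact exponential waiting time of the whole
system, and advances the membrane equation — linear while counts are
constant — by its exact exponential solution, refreshing voltage and rates
at least every 0.025 ms.  Occupancy accumulators verify stationarity
(time-averaged subunit open fractions match x∞ at a clamped voltage), and
scaling γ down by 20× drives the trace to the deterministic solution
within 1 mV on a subthreshold protocol.  IA is not included in the
stochastic model.

## Event detection and classification

Baseline = mean V over the 100 ms before pulse onset.  Excursions above
baseline + 10 mV (channel noise can reach ~5 mV) are candidate events; the
measured quantity is the half-amplitude duration ½Ad — time above
baseline + amplitude/2, with the amplitude set by the excursion's own
peak.  Two refinements make this operational on model traces:

1. stretches left between the detected runs are re-scanned at their own
   (lower) peak, so a plateau does not vanish under the overshoot of the
   action potential that launches it; runs found at this sub-level count
   only as plateaus;
2. a long-lasting run qualifies as a plateau only if V still exceeds
   −35 mV in the late half of the run — this excludes both the sustained
   passive depolarization of a pulse (a stable subthreshold fixed point,
   e.g. −40 mV) and damped subthreshold ringing, whose early peaks can
   poke above the threshold but which settles low.

Events with ½Ad ≥ 100 ms are plateaus (AP-like events here last ~10–25 ms
at half amplitude, plateaus hundreds of ms — an order-of-magnitude gap).
Descriptors: mean ½Ad; CV ½Ad (population SD/mean ×100, forced to 0 for
≤3 events); ddr = Σ½Ad / pulse duration, clipped to [0, 1].
Classification: SS = 1–3 APs and no plateau; RS = ≥4 APs, no plateau;
PP = plateaus with no spiking episodes outside them; ME = ≥1 plateau plus
≥2 APs outside plateaus; 0 events = "quiescent" (distinct from SS).  Each
plateau of the slow-inactivation model is launched by a full action
potential and rapidly decaying spikelets; AP chains that run into a
plateau with gaps ≤30 ms are absorbed into it (measured: spikelet gaps
≤23 ms, genuine inter-spike gaps in the mixed-event regime ≥36 ms).

Burst structure: hysteresis thresholding of V (threshold at 35% of the
voltage range, ±2.5 mV band) segments up/down states; phases 1–4 follow
the sign of Δs per state (1: plateau, s inactivating; 2: fall; 3:
quiescence, s de-inactivating; 4: rise).

## Population analysis

Clustering operates on (log₁₀ mean ½Ad, CV ½Ad, log₁₀ ddr), z-scored with
sample SD; complete linkage on Euclidean distances (scipy), k chosen by
maximal mean silhouette over k = 2..12 (sklearn silhouette, singleton
convention 0).  The Hill model `remaining(c) = (100−Imin)/(1+(c/IC50)^nH)
+ Imin` is fitted by bounded least squares (Imin ∈ [0, 100), IC50 > 0,
nH ∈ (0, 10]; initial guesses Imin = min response, IC50 = dose nearest the
midpoint, nH = 1), reporting residual SD and parameter SEs.

## Synthetic data

The feature-table generator draws five clusters with the reported sizes
(46 SS, 69 RS, 35 PP, 4 ME-short, 9 ME-long) at the reported centroids;
SDs are reconstructed from SEMs (SD = SEM·√n).  ½Ad and ddr are sampled
log-normally (moment-matched), CV normally truncated at 0 and set exactly
to 0 for SS and PP rows.  The two ME clusters are separated by their CV
centroids (170.9% vs 87.6%); their ½Ad/ddr centroids are placed between
the RS and PP centroids (80 ms/0.25 and 250 ms/0.35) with ~35% relative
dispersion, since only their CVs were reported as distinguishing them.
Within-cluster features are sampled independently (correlations are not
reported).  Silhouette selection recovers k = 5 in ~94 of 100 seeds.

Conductance pairs are drawn uniformly from per-phenotype boxes placed
inside the activity-map regions at I = 20 pA: SS (GNap 0.10–0.45,
GKdr 6–12 nS), RS (0.85–1.60, 7–14), PP (0.90–1.60, 1.5–2.8), ME
(1.10–1.60, 3.5–5.0 — the RS/PP boundary band).  The boxes deliberately
avoid the bifurcation lines so that simulating a sampled pair through the
step protocol recovers the generating label; the E14.5 preset shifts GNap
down (0.05–0.40) and GKdr up (8–20), placing every cell in the SS region.

Dose-response tables sample the Hill curve (defaults Imin = 5%, IC50 =
2.9 µM, nH = 1) on a 0.3–300 µM half-decade ladder with additive Gaussian
noise (default SD 5 percentage points), clipped to [0, 110].  Under that
noise a 7-dose × 3-replicate design recovers IC50 within 20% in ~89% of
fits (median error 7%), which is what the Monte-Carlo tests assert
(median < 20%, ≥80% of runs within 20%).

What the synthetic cohorts do **not** emulate: recording artefacts (series
resistance, drift), within-cluster feature correlations, and the exact
dispersion shapes of the real population — so passing tests demonstrate
that the pipeline recovers known structure at realistic noise levels, not
that it would reproduce every property of the recorded data set.

## Pharmacology

TTX zeroes GNat and GNap.  4-AP scales GKdr by the Hill remaining
fraction; it also reduces the leak (23% at 300 µM), interpolated linearly
in log-concentration from the lowest probed dose (0.3 µM, no effect) —
only the 300 µM endpoint is constrained by measurement.  The
`rheobase_matched` flag rescales the injected current proportionally to
Gin, mirroring the experimental practice of keeping the stimulus at a
comparable multiple of rheobase; with it, reducing GKdr carries an SS cell
across the repetitive-firing boundary of the (shifted) activity map.

## Known limitations

- Unstable periodic orbits and Floquet multipliers are not computed; folds
  of cycles are resolved to 10⁻³ nS by simulation, so positions carry a
  bias of that order near strongly subcritical regimes.
- The voltage clamp is ideal (no series resistance or space clamp); leak
  subtraction is exact rather than P/4-emulated.
- The ramp-based INap estimate contains the INat window current, as its
  experimental counterpart does.
- The stochastic scheme freezes rates between refreshes (≤0.025 ms);
  plateau/quiescence duration statistics under noise are therefore
  matched qualitatively, not exactly.
- No multi-compartment geometry, calcium currents, synaptic input or
  temperature scaling.
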