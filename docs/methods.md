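# Methods

## The forward model

The kinetic model tracks occupancy over a minimal set of crossbridge states:
a non-cycling reservoir, the non-force post-hydrolysis state A-M.ADP.Pi, and
the two force-bearing states AM\*.ADP.Pi and AM\*.ADP. Three structural
assumptions define it:

1. **Rapid-equilibrium Pi release.** The AM\*.ADP.Pi ⇌ AM\*.ADP + Pi step is
   assumed fast relative to the isomerization and characterized solely by
   its equilibrium constant K₂ (mM). The two AM\* states therefore form one
   lumped pool whose AM\*.ADP.Pi fraction is φ = [Pi]/(K₂+[Pi]). This is
   what gives the force-redevelopment rate its fitted functional form
   k_F = k₁ + k₋₁·φ: the pool re-enters A-M.ADP.Pi at k₋₁φ because only its
   Pi-bound fraction can reverse the isomerization. The lumping reduces the
   dynamics to three ODE states; the four-state occupancy report simply
   partitions the pool by φ.
2. **A phenomenological activation gate.** Non-cycling crossbridges enter
   the cycling pool at g_act(Ca) = g_act_max·Ca^h/(ca50_act^h+Ca^h). Whether
   this transition is cooperative through near-neighbour regulatory units is
   an open mechanistic question; the Hill form here is a gate shape, not a
   mechanism claim. Cycling bridges return to the reservoir at g_off: from
   A-M.ADP.Pi (gate closing) and from the AM\*.ADP fraction of the force
   pool (ADP release and recycling) — the latter path is what lets the model
   relax to zero force at pCa 8–9 even at zero Pi, where the k₋₁φ exit
   vanishes.
3. **Linear dynamics, exact propagation.** With a protocol-constant
   generator, trajectories are advanced by one matrix exponential per sample
   interval. This is exact for the model (no step-size control needed, no
   stiffness issues) and conserves total occupancy to floating-point
   precision; the simulator still enforces a 1e-6 conservation check and
   finiteness per step as a guard.

### Parameters, units, defaults

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| k₁ | forward Pi-isomerization rate | s⁻¹ | 26.6 | perfused-group value |
| k₋₁ | reverse Pi-isomerization rate | s⁻¹ | 42.3 | perfused-group value |
| K₂ | Pi-release equilibrium constant | mM | 39.4 | perfused-group value |
| g_act_max | maximal gate opening rate | s⁻¹ | 500 | see below |
| ca50_act | Ca²⁺ of half-maximal gate opening | µM | 3.32 | mirrors measured EC50 |
| h_act | gate Hill exponent | — | 2 | typical thin-filament cooperativity scale |
| g_off | gate closing / recycling rate | s⁻¹ | 0.5 | see below |
| f_scale | force per unit force-pool occupancy | mN/mm² | 51.3 | steady force ≈ 50 mN/mm² at pCa 4.5 |
| k_rigor_detach | rigor detachment after ATP release | s⁻¹ | 500 | fast relative to reattachment at mM ATP |

No gate kinetics are measured directly, so g_act_max and g_off are set by
two self-consistency requirements rather than by data: (i) the slowest
eigenvalue of the full generator must track the closed-form
k₁ + k₋₁φ within 5% over Pi ∈ [0, 30] mM at pCa 4.5 (g_off ≤ 0.5 s⁻¹ keeps
the recycling leak ≤ 2% of k₁), and (ii) a single-exponential fit of a
simulated Ca²⁺-jump trace must recover that eigenvalue within 5%
(g_act_max = 500 s⁻¹; at 100 s⁻¹ the gate mode contributes enough amplitude
to bias the fitted rate 14–24% low). Both requirements are enforced by the
test suite.

Conventions: pCa = −log₁₀(molar free Ca²⁺); Ca²⁺ in µM, Pi and ADP in mM;
forces in mN/mm² (cross-sectional area from two fiber diameters assuming an
elliptical section, helper provided); default sampling 1000 Hz.

### Protocol initial conditions

* **Ca²⁺ jump** (caged-Ca²⁺ photolysis) and **length release** start with
  all crossbridges non-cycling: a rapid release detaches essentially all
  bridges and regulatory units re-block, so force redevelopment and
  photolytic activation probe the same gate-plus-isomerization path. The
  model accordingly treats k_F and k_Act traces identically; the release
  step itself is not modelled mechanically — analysis starts at the
  post-release force minimum.
* **ATP jump** (caged-ATP photolysis from Ca²⁺-rigor) starts with the gate
  open and a rigor population scaled to one third of the steady active
  force, matching the roughly 1:2 rigor-to-active force partition observed
  experimentally. Rigor bridges bear force and detach at k_rigor_detach once
  ATP appears; because detachment outruns re-attachment (≈ k₁), the trace
  dips before rising — the fit window therefore starts at the trough (global
  minimum in the first 10% of the record). The trough rule is this package's
  choice; no published window convention exists for this protocol.

## Fitting

* **Single exponential** (k_Act, k_ATP, k_F): three free parameters
  (F₀, F∞, rate) — fixing F∞ at the last sample biases short records. Rate
  initialized by log-linear regression of (F∞_guess − F) with F∞_guess the
  mean of the final 10% of samples. Flat traces raise a degenerate-data
  error rather than returning a rate.
* **Hill force–pCa**: fitted per fiber (four parameters would not be
  identifiable below four points; one decade of Ca²⁺ span and genuine
  dynamic range are required). The Hill coefficient is free with start value
  2. The identity F(EC50) = Fmax/2 holds for every returned fit by
  construction.
* **Pi dependence of k_F**: bounds (0, 500] on all three parameters;
  initialization k₁ ← k_F(0), k₋₁ ← k_F(Pi_max) − k_F(0), K₂ ← median Pi.
  **Identifiability caveat:** with the experimental grid topping out at
  30 mM < K₂, k₋₁ and K₂ lie on a likelihood ridge (their ratio sets the
  initial slope; curvature separates them only weakly). A per-fiber
  five-point fit at realistic noise (SD 2 s⁻¹) does not identify K₂ —
  per-fiber estimates are wildly right-skewed and averaging them is
  misleading — so the Pi relation defaults to one pooled fit per group
  (per-fiber mode remains available, as does per-fiber Hill fitting's
  converse). Even the pooled K₂ estimator is right-skewed: across replicate
  cohorts its median sits on the truth while its mean is pulled up the
  ridge. The recovery harness therefore reports both, and the acceptance
  script uses the replicate median as the location summary for K₂.
* **Stiffness**: ordinary least squares of ΔF on ΔL over the four-release
  quadruplet; slope reported as stiffness.
* **Statistics**: pooled-variance Student's t-test by default (Welch by
  flag), two-sided; the source reports do not state sidedness or the
  variance assumption. Base α = 0.05; Bonferroni threshold α/m with m the
  number of group pairs unless overridden.

## What the synthetic cohorts emulate — and what they do not

Generators draw per-fiber measurements around the published group means:
Hill-law forces with 3% multiplicative Gaussian noise, k_F points with
additive SD 2 s⁻¹, traces with additive noise at 2% of steady force, and
densitometry signals with log-normal scatter (σ = 0.10). Published tables
report SEMs of *derived* parameters, not raw noise, so these levels are a
calibration chosen so synthetic group SEMs land near the published ones
(e.g. the k_F noise reproduces the ≈1 s⁻¹ SEM of zero-Pi rates at n = 7);
they are documented as calibration, not as measured fact. Per-fiber
parameter heterogeneity defaults to zero and is configurable (`fiber_cv`).

The generators do **not** emulate instrument artifacts (transducer ringing,
bath-change transients, baseline drift), fiber rundown across activations,
or correlated within-fiber errors. Passing recovery tests therefore shows
that the estimators are correct and well-behaved under the stated noise
model at realistic cohort sizes — not that real traces are free of the
systematic effects excluded here.

The pCa grid default {8.0, 6.5, 6.2, 6.0, 5.8, 5.6, 5.4, 5.0, 4.5, 4.0}
spans the reported experimental range with density around the EC50; only
the range, not the grid, is published. The Pi grid {0, 5, 10, 20, 30} mM is
the experimental one.

## Problem sizes

The recovery harness and acceptance script use the published cohort sizes
(n = 7 perfused, n = 10 ischemic fibers) and 40–60 replicate cohorts for
the Pi-dependence medians — enough that the replicate median of K₂ is
stable to ≈1–2 mM, with the whole computation taking seconds. Transient
cohorts use 0.5 s records at 1000 Hz, long enough that the slowest mode has
decayed by e⁻¹¹ at the record end.

## Known limitations

* No strain dependence, spatial structure, ADP-state kinetics or
  thermodynamic bookkeeping: the model is a lumped activation-plus-
  isomerization description, sufficient for the rate constants it is fitted
  to and no more. ADP-condition data are handled only as Hill-fit datasets.
* k_ATP in the model equals the cycling-subsystem relaxation rate with the
  gate open, which under the default parameters is close to the Ca²⁺-jump
  rate; the experimentally observed excess of k_ATP over k_Act reflects
  rigor-primed thin-filament activation that the single-gate model does not
  reproduce quantitatively. The ATP-jump simulation is used for its
  qualitative trace shape (rigor level, dip, recovery), not for k_ATP
  inference.
* K₂ above the sampled Pi range is intrinsically weakly identified (see
  fitting caveat); single-cohort K₂ values should always be read with their
  asymptotic SEs.
* No bootstrap confidence intervals; parameter SEs come from the fit
  curvature only.
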