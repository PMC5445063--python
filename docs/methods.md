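# Methods

## Signal model and assumptions

A lung ROI contains air, blood and tissue.  Intravenously administered
FDG contributes no airway activity, so the measured concentration is

    C_M(t) = V_B·C_B(t) + (1 − V_B − V_A)·C_T(t),

with tissue kinetics given by the irreversible two-tissue compartment
model: free compartment C1' = K1·Cp − (k2+k3)·C1, trapped compartment
C2' = k3·C1, C_T = C1 + C2.  Estimating all five of (K1, k2, k3, V_A, V_B)
from one TAC is numerically unidentifiable, so the air fraction is fixed
from CT (`V_A^CT`, linear mixing of air at −1024 HU and soft tissue at
40 HU, clipped into [0, 1] with a warning) and the remaining four
parameters are fitted.  The endpoint Ki = K1·k3/(k2+k3) is reported in
ml cm⁻³ min⁻¹; activities are kBq/ml, times minutes, and all inputs are
assumed decay-corrected to injection (standard scanner output) with t = 0
at injection.

By default one plasma-corrected blood curve serves both as the vascular
term and as the tissue-driving input; an uncorrected whole-blood curve can
be supplied for the vascular term separately (`input_blood`).

## Numerics

* **Convolution.** The 2TC response is K1·[a + b·e^(−βt)] ⊗ Cp with
  β = k2+k3, a = k3/β, b = k2/β.  On the dense 1-s grid the exponential
  convolution is evaluated exactly for a piecewise-linear input via a
  first-order recursion (implemented as an IIR filter), and the integral
  term by trapezoid — exact for the same input class.  Agreement with a
  tightly-toleranced ODE integration is ~1e-7 sup-norm; the degenerate
  trapping limit k2 = k3 = 0 uses h = K1 directly, with no division by β.
* **Frame handling.** Model curves are averaged over each frame interval
  (a precomputed quadrature matrix; frames early in the scan are tens of
  seconds long, so midpoint sampling — available as an option — is
  measurably biased).
* **qABL fit.** Bounded trust-region least squares, bounds K1 ∈ [0, 2],
  k2 ∈ [0, 5], k3 ∈ [0, 1] min⁻¹, V_B ∈ [0, 1 − V_A^CT]; 10 starts from a
  fixed-seed Latin hypercube; best converged start by weighted RSS wins.
  Default weights are frame durations (variance ∝ 1/Δt); `uniform` and
  `duration/value` are available.  An all-zero TAC is rejected as
  degenerate rather than "fitted".
* **Delay.** The blood-to-tissue delay is a grid search (−50…+50 s, 1 s)
  minimising the weighted RSS of a short model fitted to the first 5 min
  of the whole-lung TAC.  The short model is a one-tissue response plus a
  profiled fractional-blood term: the uncorrected lung TAC contains a
  direct vascular spike that a pure 1TC cannot represent, and omitting the
  blood term biases the recovered delay by several seconds (a pure-1TC
  mode is kept as an option).  The linear coefficients are profiled by
  NNLS and k2 scanned/refined in 1-D, so the search is robust and fast.
  Ties resolve toward smaller |delay|.  Positive delay = tissue lags blood.
* **IDIF reconstruction.** The aorta ROI yields frame means, which flatten
  the bolus peak.  Two lifts to the dense grid are provided: model-based
  denoising (fit the linear-rise tri-exponential bolus family to the frame
  means; default, recovers the sub-frame peak essentially exactly on data
  from that family) and a nonparametric minimum-curvature reconstruction
  constrained to reproduce the frame means with u ≥ 0 (a few sparse
  solves with active-set penalties).  The nonparametric route leaves a
  percent-level onset error that propagates into K1/k2 (not Ki).
* **Patlak.** x = ∫Cp/Cp, y = C_M/Cp at frame midpoints; unweighted OLS
  over frames that start at or after t\* (a frame straddling t\* is
  excluded); points with Cp = 0 are dropped with a flag.  nKi =
  slope/intercept; the voxelwise slope map shares x across voxels and uses
  the closed-form OLS slope.  The slope converges to (1−V_A−V_B)·Ki from
  below as t\* grows; at the default t\* = 10 min a transient bias of a few
  percent remains for slow kinetics (β ≈ 0.2 min⁻¹) — part of why the
  normalised ratio is a biased endpoint.
* **Composite algebra.** The late-time Patlak intercept of the mixture is
  (1−V_B−V_A)·V_ss + V_B with V_ss = K1·k2/(k2+k3)², the distribution
  volume the reversible compartment contributes under Patlak's asymptote.
  Truth records store this V_ss so the composite prediction can be checked
  against measured nKi directly (they agree to <1% at t\* = 40 min on the
  canonical truth).
* **Statistics.** Hedge's g with the small-sample factor J = 1 − 3/(4·df−1)
  (exact gamma form by flag) and the normal-approximation CI
  g ± z·√((n_a+n_b)/(n_a·n_b) + g²/(2·df)); published CIs come from an
  unstated CI flavour, so printed third digits are not asserted.  Classes
  small/medium/large at |g| = 0.2 and 0.8.  Pearson CI by Fisher z with
  SE 1/√(n−3).  CoV = 100·σ/μ.

## Synthetic data

The generator emulates a 60-min dynamic FDG lung protocol:

* **Frame schedule** (the acquisition protocol of the study this emulates
  is not public): 6×10 s, 4×30 s, 7×60 s, 10×300 s — a conventional
  dynamic FDG framing; fully configurable.
* **Input function**: linear-rise tri-exponential bolus (standard
  amplitudes/rates, arrival 0.5 min, peak ≈ 0.8 min at ~100 kBq/ml), or a
  simpler rise-times-biexponential, or tabulated values.
* **Groups**: healthy-like and COPD-like truths drawn from truncated
  normals matching published whole-lung summaries — Ki 6.0±1.9 vs
  5.7±1.7 ×10⁻³, V_A 0.72±0.043 vs 0.79±0.041, V_B 0.14±0.025 vs
  0.11±0.028 — parameterised as (Ki, V_ss ≈ 0.5, k2 ≈ 0.19) and inverted
  to (K1, k2, k3).  Fixed offsets modulate UL/ML/LL regions after the
  published apical-basal pattern.
* **Noise**: zero-mean Gaussian with sd = scale·√(C/Δt), the standard
  count-statistics approximation for frame-averaged TACs.  The default
  scale 0.05 reflects that whole-lung ROI means average over a multi-litre
  region: it contributes ~3% replicate noise to fitted Ki, so the
  simulated cohort's whole-lung Ki CoV (~32%) is dominated by the
  between-subject truth spread, matching the published dispersion.
* **Phantoms**: small blocks (≤ 64³ guard) whose CT values invert the
  air-fraction relation (HU = 40 − V_A·1064) so the CT route recovers V_A
  exactly; lung voxels carry the frame-averaged mixture model, a 2×2
  blood column carries the whole-blood curve, the rest is air.
* **Dissociation cohort**: both groups share identical (Ki, V_ss, k2)
  draws and paired fraction deviates; V_A/V_B sit at the published group
  means (within-group fraction dispersion is optional and off by default —
  with full dispersion the per-subject composite shift varies strongly and
  can flip sign, because its sensitivity scales with 1/(1−V_A−V_B)).  The
  designed fraction shift alone moves the normalised Patlak group mean by
  ≈ −6% (the composite prediction) while corrected Ki stays put.  Note the
  direction: with V_ss held fixed, the published fraction shift slightly
  *lowers* nKi; the larger increases reported in patient data additionally
  involve intercept/V_ss differences that pure fraction shifts do not
  produce.

All randomness in a generator call flows from one explicit seed, and truth
tables accompany every dataset.

What passing these simulations does **not** show about real data:
respiratory/cardiac motion, CT–PET misregistration, breathing-dependent
air-fraction variability, reconstruction artefacts and spatially
correlated noise are not modelled, and real input functions need not lie
in the bolus family used for IDIF denoising.

## Design choices and limitations

* The fit's weighting scheme, optimizer, bounds and multi-start layout are
  package choices; the underlying study reports none of them.
* V_A^CT is computed on whatever grid the masks live on (native by
  default); nearest-neighbour downsampling for masks and block-mean for HU
  are provided.
* The disk ROI uses an inclusion radius of (d−1)/2 voxel pitches so a
  5-voxel-diameter disk spans 13 voxels and a 1-voxel disk is its centre.
* Axial thirds cut whole slices, minimising |cumulative − k·N/3| with ties
  toward the apex; a slice holding most of the mask stays intact (logged).
* Regional fits only; voxelwise maps exist for the Patlak slope.  A
  three-tissue (extra-compartment) tissue model, appropriate for acute
  lung injury, is a documented extension point of `measured_model`, not
  implemented.
* SUV uses the duration-weighted 30–60 min mean over dose per kg; it is a
  density-confounded endpoint and is included for comparison only.
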