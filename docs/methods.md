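# Methods

## Kinetic model

The package models regional tracer kinetics with the standard two-tissue
compartment model (2TCM). With plasma-parent input C_p(t), free/non-specific
tissue concentration C₁ and specifically bound concentration C₂:

    dC₁/dt = K₁ C_p − (k₂ + k₃) C₁ + k₄ C₂
    dC₂/dt = k₃ C₁ − k₄ C₂

The tissue response to a unit plasma impulse is the biexponential
IRF(t) = φ₁e^(−θ₁t) + φ₂e^(−θ₂t) with θ₁,₂ the roots of
θ² − (k₂+k₃+k₄)θ + k₂k₄ and φ₁ = K₁(θ₁−k₃−k₄)/(θ₁−θ₂),
φ₂ = K₁(k₃+k₄−θ₂)/(θ₁−θ₂). Both amplitudes are provably non-negative for
non-negative rates, and ∫₀^∞ IRF dt = (K₁/k₂)(1+k₃/k₄) = V_T, which the test
suite checks analytically and by quadrature. When the discriminant vanishes
the response degenerates to K₁e^(−θt)(1 + (θ−k₃−k₄)t); the implementation
switches to that closed form below a relative discriminant tolerance of
1e−12 rather than dividing by a vanishing θ₁−θ₂.

The measured regional signal adds a fractional blood-volume term,
C(t) = (1−v_B)(C_p ⊛ IRF)(t) + v_B·C_wb(t), with v_B fixed at 0.05
(configurable). The convention multiplies v_B by *whole-blood* activity, the
common choice when the whole-blood curve is available. All activities are
assumed decay-corrected, so no physical-decay term appears. Times are
minutes internally; frame schedules are stored in seconds, as scanners
report them, and converted at the boundary.

Frames are reported as the *time-average* of C(t) over [t_start, t_end]
(what scanners output); midpoint sampling is available as an option and the
two agree to <0.1% for 5-s frames on smooth inputs.

## Numerical evaluation

Convolution is evaluated on the input function's uniform fine grid (default
1 s spacing) treating the input as piecewise linear. The convolution with
each exponential then satisfies an exact one-step recursion
y_i = e^(−θΔ) y_{i−1} + a₀x_i + a₁x_{i−1}, implemented as a first-order IIR
filter (`scipy.signal.lfilter`), with series expansions of the step
integrals below θΔ = 1e−8 for stability as θ → 0. The degenerate t·e^(−θt)
kernel is obtained by applying the exponential filter twice (exact in
continuous time since e^(−θt) ⊛ e^(−θt) = t·e^(−θt)). Frame averages come
from the cumulative trapezoid integral interpolated at the frame bounds;
with 1-s grids every preset frame boundary falls on a grid node. Against a
stiff ODE-solver oracle the forward model is accurate to ~1e−13 relative.

## Estimation

**Single-region 2TCM.** Weighted nonlinear least squares over
(K₁, k₂, k₃, k₄). Default weights are proportional to frame duration
(normalized), a proxy for the relative count statistics of long versus short
frames; uniform or user-supplied weights are options and the choice is
logged in run records. A constrained variant fixes V_ND and fits (k₂, k₃,
k₄) with K₁ = k₂·V_ND.

**SIME.** The joint cost is the plain sum of squared residuals across all
regions (unweighted by default, matching how the shared-volume cost is
usually posed; weights are optional) over {k₂ʳ, k₃ʳ, k₄ʳ} ∪ {V_ND} with
K₁ʳ = k₂ʳ·V_ND. At least four regions with a spread of kinetic behaviour
are expected; with three or fewer the shared volume is weakly identified and
the model warns (and in practice often fails).

Three routes:

* **optimizer** (default): bounded trust-region reflective least squares
  (`scipy.optimize.least_squares`, ftol = xtol = 1e−12, up to 5000 residual
  evaluations) with multi-start — the nominal literature-scale start plus
  seeded log-normal perturbations (default 3 starts; ties broken by lowest
  cost, then lowest V_ND). The joint cost is smooth, and the trust-region
  route converges more reliably and roughly an order of magnitude faster
  than a 19-parameter simplex, which is what makes the replicate-level
  Monte Carlo tractable on one CPU.
* **simplex**: bounded Nelder–Mead on the identical cost via a sine
  transform of the box constraints, provided as the historically used
  derivative-free alternative.
* **grid**: profile search — for each V_ND candidate (default 0.5 to 6.0
  ml/cm³ in 0.05 steps) the per-region triples are re-fitted with
  K₁ = k₂·V_ND, warm-starting each candidate from its neighbour; the
  candidate with the lowest total cost wins. Optional parabolic refinement
  through the minimum is off by default. The grid route is retained as an
  independent cross-check of the optimizer (they agree within one grid step
  on noiseless data, and to ~0.5% mean on noisy data).

Bounds: k₂, k₃, k₄ ∈ [1e−6, 2] min⁻¹, V_ND ∈ [0.1, 10] ml/cm³ (K₁ implied);
initial values k₂ = 0.1, k₃ = 0.05, k₄ = 0.03 min⁻¹, V_ND = 2.0 ml/cm³,
consistent with published TSPO-tracer magnitudes. A fit is flagged
`at_bounds` when any parameter sits within tolerance of a bound; a SIME run
is declared failed when no start converges or more than half the regional
fits sit on bounds.

**Scan truncation** keeps only frames wholly inside the window
(frame_end ≤ duration), avoiding partially acquired frames. The background
(pre-injection) frame of the HRRT protocols is excluded from the presets
altogether, so fitting never sees it.

## Blood models and input construction

* **Blood-to-plasma ratio**: BPR(t) = A₁e^(−λ₁t) + A₂e^(−λ₂t), amplitudes
  and rates bounded below by zero (a plateau is λ→0), fitted to
  whole-blood/plasma activity ratios by multi-start bounded least squares
  (3 fixed-seed starts). Rates are reported in λ₁ ≥ λ₂ order. With only
  positive-time samples the fit can place a fast component that dies before
  the first sample; the curve is therefore only constrained over the
  sampled range.
* **Parent fraction**: f(t) = 1 − (1−a)t^b/(c+t^b) with plateau a ∈ [0,1],
  slope b > 0 and scale c > 0 (units min^b). This parameterization fixes
  f(0) = 1, is monotone non-increasing, and tends to a — the boundary
  behaviour parent-fraction data imply. (The exact parameterization used in
  any given lab is rarely printed; this is the standard choice.)
* **Metabolite correction**: C_p(t) = C_wb(t)/BPR(t) · f(t) on the curve's
  grid; evaluation refuses any BPR ≤ 0.
* **IDIF scaling**: an image-derived whole-blood curve is anchored to late
  venous whole-blood samples (default 45/60/90 min, when venous and
  arterial concentrations have equilibrated) by the single factor
  s = Σvᵢuᵢ/Σuᵢ² minimizing the same L2 criterion used everywhere else (not
  the mean of ratios); s is returned alongside the scaled curve, and
  re-scaling against the same samples yields s = 1.
* **Venous–arterial agreement**: ordinary least squares of venous
  (response) on arterial (predictor) — the orientation is recorded in the
  output — with Pearson r² and a two-sided t test of slope = 1. With an
  exact noiseless line the slope standard error is zero and the p-value is
  defined as 1 when the slope is exactly one, else 0.

### A note on input-scaling invariance

BP_ND is invariant to a scaling error in the *plasma* input: multiplying
C_p by s is exactly absorbed by K₁ → K₁/s (hence V_ND, V_T → /s) with
k₂, k₃, k₄ unchanged. This exactness does **not** extend to scaling the
whole-blood curve as well, because the fixed v_B·C_wb term in the measured
signal does not rescale; a global whole-blood scaling therefore perturbs
the fit (noticeably so around the bolus peak). The property tests
accordingly scale the plasma-parent curve only, which is the error mode the
ratio-based BP_ND is designed to tolerate; linearity of the forward model
in *both* curves is tested separately.

## Synthetic data

The generator emulates a 90–180 min TSPO-tracer study:

* **Input function**: a gamma-variate bolus A(t/t_p)^α e^(α(1−t/t_p))
  peaking at t_p (default 1 min, 45 kBq/ml, α = 3) plus a biexponential
  recirculation washout (defaults 4.0 kBq/ml at 0.15 min⁻¹ and 2.5 kBq/ml
  at 0.005 min⁻¹); before the peak the washout rises in proportion to the
  bolus so the curve's maximum stays exactly at t_p. Synthetic BPR and Hill
  models (BPR from 1.15 to a 0.85 plateau; parent fraction falling to a 7%
  plateau with slope 1.5, scale 60 min^1.5) convert whole blood to a
  consistent plasma-parent curve. These magnitudes were chosen once as
  representative of [¹⁸F]FEPPA-like kinetics and are recorded in
  `InputParams`.
* **Truth**: six regions share V_ND = 2.35 ml/cm³ with total volumes
  14.30/15.16/11.69/11.80/15.10/13.80 ml/cm³ (frontal, temporal,
  cerebellum, thalamus, insula, caudate). The volumes do not determine k₂
  and k₄, which are fixed at 0.1 and 0.047 min⁻¹; k₃ follows from
  k₃/k₄ = V_T/V_ND − 1.
* **Noise**: frame-wise Gaussian with SD = (profile level) × (TAC mean
  activity) — i.e. scaled to the *mean* activity, the normalization used
  for measured residual profiles — independent across frames and regions,
  not clipped at zero. `residual_profile` builds an empirical profile from
  measured-vs-fitted TAC pairs (mean over subjects of |residual|/mean);
  the shipped defaults are a flat 5% relative SD, or 5% with 10% on frames
  shorter than 30 s. One master seed drives everything; each Monte Carlo
  replicate uses the substream (seed, replicate) so any replicate can be
  re-run in isolation.

What the synthetic conditions do *not* emulate: count-rate–dependent frame
variances, covariance between regional TACs (measured residual correlations
in real data are weak to moderate, so independent noise is a reasonable
approximation, but it is an approximation), delay/dispersion of the input,
partial-volume or spill-in effects on IDIFs, and subject-to-subject kinetic
variability. Passing recovery tests therefore demonstrates estimator
correctness and precision under the stated noise model, not performance on
real data.

## Reference experiments and problem sizes

`simepet.benchmarks` fixes two canned experiments, both run by
`scripts/acceptance.py` and the acceptance tests:

* **BP_ND recovery bias**: 200 replicates of the six-region study at 5%
  flat noise on the 52-frame 90-min schedule; reported as the mean over
  regions of 100·|mean(BP_ND) − true|/true. 200 replicates keep the
  experiment to a few minutes on one CPU while the Monte Carlo standard
  error of the reported mean is well below the quantity itself.
* **Grid vs optimizer**: 20 noisy datasets, V_ND estimated by both routes
  (grid 0.5–6.0, step 0.05), reported as the mean relative difference.

Under these conditions V_ND and V_T are recovered essentially without bias
(<0.5%), while the *mean* of BP_ND = V_T/V_ND − 1 inherits a small positive
bias of order CV² from the convexity of the ratio in V_ND (V_ND COV ≈ 10%
at this noise level ⇒ ≈1–2% BP_ND bias). The effect is structural — it is
unchanged by adding optimizer starts — and shrinks quadratically as noise
falls; with a measured (lower, frame-dependent) residual profile in place
of the flat 5% default it is correspondingly smaller.

## Known limitations

* Derivative-free simplex fitting is available but slow at SIME dimension;
  the default trust-region route assumes a smooth cost (true here).
* The BPR and Hill fits are constrained only at the sampled times;
  extrapolation before the first sample is unreliable.
* No delay/dispersion correction of input functions; no voxelwise
  (parametric-image) fitting; no metabolite-pool modelling inside SIME;
  reversible one-tissue and graphical (Logan) variants are out of scope.
* BP_ND summaries over noisy replicates carry the ratio-convexity bias
  described above; V_S and V_T are the better-behaved accuracy metrics.
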