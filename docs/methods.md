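# Methods

`neuropk` models the transit of an intravenously dosed drug (the
motivating case is the cephalosporin cefepime in the rat) from plasma
into cerebrospinal fluid (CSF), estimates the between-animal
distribution of the kinetic parameters nonparametrically, and derives
per-animal exposure and CSF-penetration statistics from MAP Bayesian
posterior concentration profiles. This note records the model, the
algorithmic choices, the synthetic-study generator that stands in for
raw animal data, and the limits of what the package's own validation
can show.

## Compartmental model

Drug amounts X (mg) follow a linear system dX/dt = A·X + u(t). The full
structure has four states: central (plasma, volume Vc), peripheral,
an unobserved lag state, and CSF (volume V_CSF):

    dX1/dt = u(t) − (kel + K12 + K13)·X1 + K21·X2 + K41·X4
    dX2/dt = K12·X1 − K21·X2
    dX3/dt = K13·X1 − K34·X3
    dX4/dt = K34·X3 − K41·X4

Plasma concentration is X1/Vc, CSF concentration X4/V_CSF (mg/liter ≡
µg/ml). Elimination (kel) leaves only from the central compartment.
The lag state delays drug arrival in CSF without itself being observed.
u(t) is a zero-order infusion: the 2-minute IV push is modelled as a
1/30-h infusion, not a bolus, because the peak concentration is
sensitive to the administration duration. Time zero is the start of the
first dose; units are hours, mg, liters throughout, chosen so that
concentrations, AUCs and rate constants compose without conversion
factors.

Three simpler nested structures are provided for model comparison:
`two_compartment` (central + CSF, exchange K13/K41),
`three_compartment` (adds the peripheral compartment; CSF exchange uses
a single symmetric constant K13), and `three_compartment_lag_constant`
(same three states with a distinct return constant K41). Only the
four-compartment lag structure is exercised by the validation studies;
the three-state wirings are the minimal nestings consistent with a
(5, 6, 7, 8)-parameter ladder and are not canonical.

### Exact solution

Within any interval where the infusion input is constant, the exact
update of the state is the exponential of the augmented matrix
[[A, u], [0, 0]]. The public solver walks the merged breakpoints (dose
starts/ends and query times) and applies this update per segment;
superposition over doses and linearity in dose hold to floating-point
accuracy by construction.

The population fitter evaluates thousands of candidate parameter
vectors against every subject. For that path the stacked rate matrices
are diagonalized once per candidate batch (`numpy.linalg.eig` is
batched LAPACK) and propagation happens in eigen-coordinates at
elementwise cost; the φ₁(z) = (e^z − 1)/z factor handling the infusion
input switches to a Taylor series below |z| = 1e−4. Any matrix whose
eigenvector basis is ill-conditioned (condition number > 1e10 —
repeated or near-defective eigenvalues) silently falls back to the
augmented `scipy.linalg.expm` path, so correctness never depends on
diagonalizability. The two paths agree with an independent adaptive
Runge–Kutta integration (DOP853, rtol 1e−12) to better than 1e−6
relative over random parameter draws spanning the full search box; in
that comparison the denominator is floored at 1e−6 of the administered
dose, because amounts that have decayed to ~1e−14 mg carry only
floating-point noise in either method.

## Observation model and likelihood

The assay error is a linear polynomial in the observed concentration,
SD(Y) = C0 + C1·Y per matrix, with defaults C0 = 0.25, C1 = 0.15
(plasma) and C0 = 0.0625, C1 = 0.15 (CSF) µg/ml — the reported
calibration of the LC-MS/MS assay in each matrix — inflated by a single
multiplicative scalar γ shared across channels (default 1, optionally
re-estimated once per fitting cycle by one-dimensional likelihood
maximization). Observations are independent Gaussians on the
concentration scale (the SD polynomial is defined on that scale, so no
log transform is used); Y in SD(Y) is the *observed* value, which makes
each observation's SD a constant of the data and the subject
-2 log-likelihood a weighted sum of squared residuals plus a constant.
Excluded observations (for instance a manually flagged 100-fold
outlier) contribute nothing.

Model comparison uses AIC = −2LL + 2p with p = number of active
structural parameters + 1 for γ. Predictive performance is summarized
per channel by the weighted mean prediction error (bias), the
bias-adjusted weighted mean squared error (imprecision), and the R² of
an observed-versus-predicted ordinary least-squares regression with
intercept. Weights are 1/SD² by default; unit weights are available
(`weighting="unit"`) because reporting conventions differ between
analysis suites.

One consequence of the proportional error worth noting: the normalized
residual of any single observation against a near-zero prediction is
bounded near C1⁻¹·(1 − C0/…) ≈ 6.7, so a handful of wild values can
never drive a subject's density to exactly zero. The fitter's
"no finite-likelihood point" diagnostic therefore triggers on absolute
underflow (best log-likelihood below −700), which in practice requires
an additive-error configuration or a large, internally inconsistent
dataset.

## Nonparametric population estimation

The between-subject distribution of the parameter vector is estimated
as a discrete mixture: support points θⱼ with probabilities wⱼ chosen
to maximize Σᵢ log Σⱼ wⱼ·L(subjectᵢ | θⱼ). This is the nonparametric
maximum-likelihood problem; the optimal mixing distribution is discrete
with at most N support points, which motivates the adaptive-grid
family of algorithms.

A fit runs as follows:

1. **Initialization.** A scrambled-Sobol grid of `n_init` (default
   2048) points fills the search box log-uniformly. The default box is
   [m/10, 10·m] around the published population medians — it contains
   every reported median with an order of magnitude of margin on each
   side; no search ranges were published.
2. **Weights.** Mixture weights are optimized by EM multiplicative
   updates, which are monotone from any interior start; convergence is
   declared at simplex-gradient (KKT) tolerance 1e−8. Inside cycles the
   update count is capped at 2000 for speed; a final full-tolerance
   pass runs after the last cycle. A brute-force simplex mesh search
   cross-checks the optimizer on a 5-point problem in the test suite.
3. **Condensation.** Points below `condense_tol` (1e−8) of the total
   mass are dropped and numerically identical points merged.
4. **Expansion.** Each surviving leading point (the top-weight points
   covering ≥ 1−1e−6 of the mass, at most 200 — flat likelihood ridges
   otherwise litter the support with near-duplicates whose perturbation
   adds nothing) is perturbed along each axis, both directions, by a
   fraction of the log-box width. The fraction starts at 20% and halves
   whenever a cycle fails to improve −2LL by `convergence_tol` (0.01);
   the fit stops when it would shrink below `min_expansion` (1e−3).
   Halving on stall rather than every cycle matters: an unconditionally
   shrinking step strands the support far from the optimum whenever the
   initial grid is not already close.
5. **Relocation (EM M-step).** Axis-aligned steps cannot follow
   correlated ridges — moving kel alone is never favourable if Vc and
   K12 must move with it. Each cycle the leading points are therefore
   also relocated by a bounded quasi-Newton search (L-BFGS-B in log
   space, numeric gradients; Powell selectable) maximizing their
   responsibility-weighted log-likelihood, which is exactly the M-step
   of EM for a point-mass mixture. At equal wall time the quasi-Newton
   M-step reaches substantially deeper mixture likelihoods than a
   direction-set search, and on ridge-shaped problems the depth of the
   optimum is what determines whether the weakly identified parameters
   land near truth. Relocated points enter the candidate
   pool on the same terms as expanded ones.
6. **Acceptance.** The enlarged support is kept only if the
   re-optimized −2LL does not increase, so the −2LL trajectory across
   accepted cycles is non-increasing by construction (asserted on every
   fit in the test suite).

All stochastic steps derive from a single required integer seed;
refusing to default the seed is deliberate, since reproducibility of a
fit is the package's purpose. The fitter is an sklearn-style estimator
(`NPAG`), so `get_params`/`set_params`/`fit` compose with generic
tooling; `fit_population` is the functional wrapper.

## Posteriors, exposures, penetration

Per-subject posteriors follow by discrete Bayes over the fitted support
(posterior ∝ prior × likelihood). A subject with no usable observations
keeps the population prior (with a warning) — this mirrors how animals
whose CSF catheter failed before any sample still receive CSF exposure
estimates from the population model, while being excluded from
penetration summaries.

Posterior concentration profiles are evaluated on a 12-minute grid
(0 to 24 h inclusive, 121 points). At each grid time the support-point
predictions are pooled with the *posterior-weighted median* (lower
weighted median: smallest value whose cumulative posterior reaches
0.5). The weighted mean and the single maximum-posterior point are
selectable alternatives; the median was chosen as the default reading
of "median MAP Bayesian estimates", and the choice is configurable
precisely because that phrase is ambiguous.

From each profile: AUC(0–24) by the trapezoidal rule on the grid;
Cmax/Tmax as the grid maximum and the earliest time attaining it
(on the 12-min grid a post-infusion plasma peak lands on 0.2 h);
terminal half-life as ln 2/k with k from a log-linear least-squares fit
of the last three grid points of the 0–8 h window. CSF penetration is
100 × CSF/plasma exposure ratio, by AUC and by Cmax, rounded half-up to
integer percent for display; unrounded ratios are retained. Cohort
summaries report median, IQR and CV% (= 100·SD/mean, sample SD).
Quantiles use the (n+1)p plotting position — the convention of the
summary software behind the reference table, and the only common
convention that reproduces all of its printed IQR endpoints at n = 7
(the default linear-interpolation rule of numpy does not). Penetration
medians are computed on the rounded integers by default (reproducing
the printed summaries); raw-ratio summaries are a flag away.

The packaged reference table (11 animals, transcribed at printed
precision, with a flag for the four animals that contributed no CSF
sample) is checksummed; `reproduce_table3_summaries` recomputes every
derived cell from the per-animal inputs and reports pass/fail per cell.

## Synthetic-study generator

No raw concentration data are deposited with the motivating study, so
the generator emulates its design and is the basis of every
recovery claim:

- 11 animals, weights Normal(306 g, 25 g) — the published cohort mean;
  the spread is a plausible adult-male value, not a published one.
- 150 mg/kg IV over 2 min once daily for 4 days (45.9 mg per dose at
  306 g).
- 9 plasma samples per animal, 5 in the first 24 h (0.2, 0.5, 1, 2,
  4 h, then 4 staggered draws over days 2–4); CSF at 1 and 2 h on day
  1 and 4 staggered later samples (2 in the first 24 h, 6 total). The
  per-animal stagger cycles through {0, 0.5, 1, 1.5} h. The published
  staggered schedule is not machine-readable; this emulates its stated
  marginal counts, not its exact cells.
- True parameters per animal are independent log-normals with median =
  the published population medians and CV% per parameter (log-normal:
  µ = ln m, σ² = ln(1 + cv²)).
- Noise: observed = truth + Normal(0, SD(truth)·γ), resampled once if
  negative and then clamped at zero — a documented deviation from pure
  Gaussian noise needed to keep concentrations valid. Values below the
  assay LLOQ (0.5 plasma / 0.125 CSF µg/ml) are flagged but reported
  and fitted; no BLQ rule is imposed.
- Artifacts: each animal's CSF record is wiped with probability 4/11
  (catheter failure), and with probability 1/11 one plasma value is
  multiplied by 100 and left unflagged — detecting it is downstream
  quality control (`flag_gross_outliers` implements the manual rule).

Ground truth (true parameters, noise-free concentrations) is returned
in separate `TruthRecord` objects that never enter the fitting path.

A second, dense design (`rich_design`: single dose, 12 plasma + 8 CSF
samples per animal, no artifacts) backs the parameter-recovery and
end-to-end checks. Its schedule is identifiability-driven: plasma
sampling starts at 0.05 h because the distribution half-life
ln 2/(K12+K21) is ≈ 41 s and without draws inside the distribution
phase Vc and kel are only jointly identified (fits slide 40% along the
ridge with no likelihood penalty); sampling stops at 6 h because the
true profile falls below the assay quantitation limit by ≈ 5 h, and
zero-truncated noise-floor samples otherwise bias the washout slow.

### What the synthetic studies do and do not show

Passing recovery tests show that the estimator recovers the generating
distribution *under the package's own error model and design* — the
noise really is the SD polynomial, parameters really are independent
log-normals, the structural model really generated the data. Real
animal data violate all three (correlated parameters, model
misspecification, assay drift, BLQ censoring), so recovery here bounds
estimator error from below, not analysis error on real data. The
published fitted values that depend on the undeposited raw
concentrations (the model-comparison table, the population medians as
fit outputs, the observed-versus-predicted diagnostics) are
correspondingly *not* reproduction targets; the published per-animal
exposure table and its summary arithmetic are, and reproduce exactly.

Known identifiability limits at this design, visible in the synthetic
studies: K13 and V_CSF are individually much weaker than their ratio
(the CSF amplitude); K34/K41 have a flip-flop symmetry broken only by
the CSF-to-central return flux; K12/K21 beyond their ratio are carried
by a few very early samples. The recovery check (weighted medians of
kel, Vc, K13, K34 within 25%) sits above the ~10% sampling error of a
25-animal median at 25% CV, but kel is the least stable of the four:
the mixture likelihood has near-equivalent optima (within ~2-5 -2LL
units over 25 subjects) whose kel medians differ by ±30%, and which
basin a run lands in depends on the starting grid. Likelihood depth
does not select among them, so this is intrinsic nonparametric-MLE
variability at this design and noise level, not an optimizer artifact;
repeat runs at other generator seeds can land outside the 25% band on
kel while every other check holds.

## Problem sizes and tolerances

Validation studies run at sizes a reviewer can reproduce on a laptop
core: the solver oracle uses 100 random draws; the optimizer
cross-check a 5-point support on 4 subjects with a mesh-refined
brute-force search down to step 1e−3; the recovery and end-to-end
study 25 animals, `n_init` 2048, up to 100 cycles (a few minutes).
Tolerances: solver agreement 1e−6 relative (dose-scale floor as above);
weight-optimizer gap 0.01 in −2LL; recovery 25% relative on the four
key parameter medians; end-to-end median AUC-penetration within 5
percentage points of the generating truth; −2LL monotone on every fit.

## Known limitations

- Linear kinetics only; no saturable transport, no protein-binding
  correction, no meningeal-inflammation effects on transit.
- The EM/adaptive-grid optimizer is a desk-scale implementation: it is
  monotone and cross-checked, but it is not the interior-point NPAG of
  the production pharmacometric suites, and on hard ridges it stops at
  a local nonparametric optimum.
- γ estimation is a single shared scalar; per-channel γ or additive
  versus proportional error selection is out of scope.
- The weighted-median profile aggregator is a convention; exposures
  from strongly multimodal posteriors depend on it (the alternatives
  are provided).
- BLQ observations are fitted at face value; a censored likelihood is
  not implemented because no BLQ rule is stated for the reference
  analysis.
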