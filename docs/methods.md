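# Methods

## The scientific question

Face aftereffects — the change in a face's perceived age after prolonged
exposure to an adapting face — are used to arbitrate between two accounts of
how the visual system encodes faces. Under **norm-based coding
(renormalization)**, faces are represented relative to a prototype;
adaptation shifts the prototype toward the adaptor, so all test faces are
biased by roughly the same constant amount, with no aftereffect when
adapting to the norm itself, and opposite-direction biases for adaptors on
opposite sides of the norm. Under **multichannel coding (local repulsion)**,
faces are encoded by channels tuned to absolute age; adaptation locally
repels test ages away from the adaptor, in opposite directions on either
side of it, with a null exactly at the adapting age and the same pattern at
every adapting level.

The package implements the model-comparison analysis that separates these
accounts on per-face aftereffect data: each data point is one test face in
one adapting condition (young / middle / old), characterized by its
pre-adaptation perceived age `pre` and its aftereffect `post − pre`, both in
years. All model predictions are functions of the pre-adaptation *perceived*
age, not the physical stimulus age, because perceived age is the scale on
which observers report.

## Models

**Renormalization** (1 free parameter). The aftereffect is constant across
test ages and proportional to the adaptor's distance from the norm:

    Δ(t) = k · (norm_age − adapt_age)

with dimensionless gain `k`. The norm defaults to the middle adapting age
(57 y), since middle-aged faces act as the perceptual norm for age; it is
configurable. Adapting at the norm predicts exactly zero aftereffect, so in
the middle condition this model coincides with the no-aftereffect baseline.

**Constrained repulsion** (2 free parameters). A Gaussian-derivative (GD)
aftereffect shape shared by all conditions,

    Δ(t) = A · √e · u · exp(−u²/2),   u = (t − μ) / σ,

with the zero-crossing μ *forced* to each condition's adapting age and a
single amplitude `A` (years) and bandwidth `σ` (years) across conditions.
The √e factor normalizes the shape so the extrema equal exactly ±A at
μ ± σ; `A` therefore reads directly as the peak aftereffect. Pinning the
null and sharing (A, σ) are what make this a *model* of repulsion rather
than an arbitrary curve: a mechanistic channel account requires the null at
the adaptor and comparable adaptation strength/spread at every level.

**Unconstrained per-condition GD** (3 parameters per condition). The same GD
with `A`, `σ`, and `μ` all free, fit separately to each condition, with μ
bounds deliberately wide (−50 to 150 y) so optima may drift to implausible
null ages outside the stimulus range. This replicates the curve-fitting
procedure whose drifting nulls and wildly inconsistent bandwidths motivate
the constrained model; it is provided for inspection, not as a candidate
model. A diagnostic property, exercised in the tests: a GD with very broad
tuning approximates a straight line over a finite age range, so
unconstrained fits to locally linear aftereffect patterns are expected to
return large σ and, when the data do not cross zero inside the range, a
zero-crossing outside it.

## Fitting

- Renormalization is linear in `k` and solved in closed form,
  `k = Σ yᵢdᵢ / Σ dᵢ²` with `dᵢ = norm − adaptᵢ`; middle-condition points
  (d = 0) contribute residuals against a zero prediction but no information
  about `k`.
- The GD fits minimize pooled squared residuals with bounded trust-region
  least squares (`scipy.optimize.least_squares`, `ftol = 1e-8`). Bounds:
  A ∈ [−20, 20] y, σ ∈ [1, 100] y, μ ∈ [−50, 150] y (unconstrained fit
  only). Residuals are computed on per-face mean aftereffects; per-observer
  weighting is out of scope.
- Multi-start strategy. For a fixed shape the amplitude is linear, so every
  restart begins at its closed-form amplitude. Restart σ values are the
  fixed grid {2, 5, 10, 20, 40, 80}; for the constrained fit this grid is
  augmented with the local minima of the amplitude-profiled SSE scanned over
  199 equally spaced σ values, because the profiled SSE can have several
  basins on weak-signal data and a coarse grid alone was observed to miss
  the global basin by ~1% SSE. The unconstrained fit crosses the σ grid with
  μ starts every 10 years across the μ bounds. Restarts are ranked by SSE;
  ties (relative tolerance 1e-9) break deterministically to smallest σ, then
  smallest |A|.
- Degenerate inputs: with all-zero aftereffects the fitted amplitude is 0
  and σ is unidentifiable; the fit reports σ at its initialization together
  with an explicit unidentifiability message rather than failing. Fits with
  no converged restart raise with per-restart diagnostics.
- OLS (`fit_linear_regression`) delegates to `scipy.stats.linregress`;
  constant-x input raises a degenerate-regression error. Intercepts are
  reported at age 0, the conventional OLS intercept; the alternative
  (evaluating at the range minimum, 18 y) would change intercept values but
  none of the sign conclusions, which is what the diagnostics rest on.

## Model comparison

Models are scored by RMS residual per condition and pooled ("combined"),
against a **no-model baseline** (zero predicted aftereffect — the root mean
square of the raw aftereffects). Both fitted models nest the zero model
(A = 0, k = 0), so their RMS never exceeds the baseline on the data they
were fit to.

The two models are compared by a paired **Wilcoxon signed-rank test** on the
per-point absolute residuals `|obs − pred|`, paired by data point. "Relative
errors" is interpreted as these absolute-residual differences — the most
common reading; the signed-residual alternative was considered and rejected
because it conflates error magnitude with bias direction. Zero differences
are dropped (standard convention); tied magnitudes receive midranks. For
n ≤ 12 usable pairs the two-sided p is computed by exact enumeration of all
2ⁿ sign assignments; for larger n the normal approximation is used with the
tie-corrected variance and a 0.5 continuity correction. z is signed so that
positive z means the repulsion model has the larger errors. The combined
scope pools all three conditions' points, middle included. `better_model` is
the lower-RMS model when p < α (default 0.05), else a tie. Rank tests are
used instead of AIC/BIC-style penalties so the comparison makes minimal
assumptions and does not charge the repulsion model for its extra parameter.

## Regression-line diagnostics

`intercept_curve` quantifies the discriminating signature. For each
bandwidth σ, the GD aftereffect curve (peak ±2.4 y, null at the condition's
adapting age) is evaluated at integer ages 18–89 (72 points — integer ages
are the natural sampling unit; continuous integration would change
intercepts only in the third decimal) and an unweighted OLS line is fit.
Repulsion with positive amplitude always yields *negative* intercepts and a
*positive* slope change at every adapting level; uniform renormalization
instead shifts the intercept by exactly the constant aftereffect —
+2.4 / 0 / −2.4 y for young / middle / old adaptors — with no slope change,
i.e. *opposite-signed* intercept shifts for young versus old. The default σ
grid {2, 5, 10, 20, 30, 40, 48, 50, 80} spans the bandwidths that
unconstrained per-condition fits can return (from a few years to several
decades).

## Synthetic data generator

The original per-face rating data are not deposited, so the generator
emulates the study design: per condition, true pre-adaptation perceived ages
tile 18–89 y evenly with uniform jitter of up to half the grid spacing; the
truth model (renormalization, repulsion, or none) assigns each face its
noiseless aftereffect at its true pre age; each simulated observer
contributes a pre rating `pre + N(0, pre_sd)` and a post rating
`pre + Δ + N(0, post_sd)`, and recorded pre/post ages are across-observer
means. The recorded aftereffect therefore has noise SD
`√(pre_sd² + post_sd²)/√n_observers` around the truth curve (tested at that
formula). Defaults: 24 faces per condition, one observer, post-rating noise
SD 3 y, no pre-rating noise, truth gain k = 0.1 (young-condition shift
+2.2 y) or truth GD (A = 2.4, σ = 20). The noise default is a calibration
choice: it places synthetic no-model RMS values in the ~2.5–3.5 y range
typical of per-face age-rating scatter. With both noise sources active the
recorded pre age and the aftereffect are negatively correlated (regression
to the mean), as in real settings; the pre age is used as the regressor
without measurement-error correction, matching the original analysis.

What the generator does **not** emulate: individual-observer response
processes (lapses, scale compression, criterion drift), heteroscedastic
rating noise across age, non-uniform face sampling, and any face-identity
structure. Passing tests therefore certify the pipeline's statistical
machinery under the stated noise model, not conclusions about human data.

## Known limitations

- **Single-dataset model-selection power is low at the default noise
  level.** A constrained GD with σ near its 100-year bound closely mimics
  constant per-condition shifts over a 71-year test range (noiseless
  residual RMS ≈ 1.2 y against a renormalization signal of RMS ≈ 1.35 y), so
  with 3-year rating noise and 24 faces per condition the combined
  signed-rank z under renormalization truth is ~1.2 on average and the test
  selects the true model in a minority of replicates (measured ≈ 15% under
  renormalization truth, ≈ 50–56% under repulsion truth, ≈ 99% ties under a
  no-effect truth). This mimicry — a broad, remote-null GD approximating a
  locally linear or constant change — is intrinsic to the models over a
  finite age range, not an artifact of the optimizer (which matches a dense
  grid oracle to ~1e-10 relative SSE) or of the test (which matches an
  independent signed-rank implementation to machine precision). Distinguishing
  the models reliably at this noise level requires more faces, more
  observers per face, or pooling across datasets.
- The middle condition carries no information about the renormalization gain
  and little about the comparison (the renormalization prediction there is
  identically zero).
- Parameters are point estimates; no confidence intervals or Bayesian
  posterior are provided.
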