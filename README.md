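# ageadapt

Model comparison for facial age-adaptation aftereffects: does adapting to a
face of a given age **renormalize** perceived age (a norm-based code — all
faces shift by a constant amount, in opposite directions for young vs. old
adaptors, with no effect of adapting to the norm) or **locally repel** it (a
multichannel code — test ages are pushed away from the adaptor on either
side, with a null at the adapting age)?

The package is for visual psychophysicists analyzing pre/post age-rating
experiments: per-face records of the pre-adaptation perceived age and the
aftereffect (post − pre, in years) under young / middle / old adapting
conditions. It provides:

- **Models.** Renormalization, `Δ(t) = k·(norm − adapt)` (one free
  parameter), and constrained Gaussian-derivative (GD) repulsion,
  `Δ(t) = A·√e·u·exp(−u²/2)` with `u = (t − μ)/σ`, the null μ pinned to each
  condition's adapting age and (A, σ) shared across conditions (two free
  parameters). The √e scaling makes the extrema exactly ±A at μ ± σ.
- **Fitting.** Closed-form gain for renormalization; multi-start bounded
  least squares for the GD fits, including the *unconstrained* 3-parameter
  per-condition fits whose implausible nulls (e.g. zero-crossings at
  negative ages) motivate constraining the model.
- **Comparison.** RMS error per condition and combined against a zero-
  prediction baseline, plus a paired Wilcoxon signed-rank test on per-point
  absolute residuals (exact for ≤ 12 pairs, tie- and continuity-corrected
  normal approximation otherwise).
- **Regression diagnostics.** Intercepts of OLS lines fit to GD curves
  across bandwidths vs. the uniform-renormalization references (+A / 0 / −A),
  and pre-vs-post slope/intercept-change analysis.
- **Synthetic observers.** A seeded generator producing datasets with the
  study's structure under either truth model, for power analysis and
  end-to-end testing.

See `docs/methods.md` for the models, estimation details, the generator's
assumptions, and known limitations (notably the low single-dataset power to
discriminate the models at realistic rating noise).

## Worked example

Simulate a default dataset (24 faces per condition, renormalization truth
with gain k = 0.1, 3-year rating noise), fit both models, and compare:

```bash
ageadapt run --seed 1 --out results/demo
```

```
scope       RMS norm   RMS rep  RMS none       z        p    n  better
----------------------------------------------------------------------
young          2.340     2.969     3.115    1.56    0.119   24  tie
middle         3.267     3.282     3.267    0.84    0.399   24  tie
old            3.444     3.564     3.562    1.16    0.247   24  tie
combined       3.056     3.281     3.320    1.97   0.0486   72  normalization
```

Each row scores both fitted models by RMS residual (years) against the
no-model baseline; `z` is the signed-rank statistic on paired absolute
residuals (positive = repulsion has larger errors) and `better` names the
lower-RMS model when p < 0.05, else `tie`. Here the combined test just
rejects, in favor of the true (renormalization) generating model; note the
middle condition, where the renormalization prediction is identically zero,
matches the no-model RMS exactly. Artifacts (`ratings.csv`, `fits.json`,
`fitted_curves.csv`, `report.json`) are written under `results/demo`.

The intercept diagnostic:

```bash
ageadapt fig1 --out intercepts.csv
```

```
young: renorm reference intercept +2.40; GD intercepts -0.068, -0.423, -0.990, ...
middle: renorm reference intercept +0.00; GD intercepts -0.068, -0.427, -1.694, ...
old: renorm reference intercept -2.40; GD intercepts -0.068, -0.427, -1.600, ...
```

Repulsion drives the regression intercept *negative at every adapting age*
regardless of bandwidth, while renormalization predicts opposite-signed
intercept shifts for young (+2.4) vs. old (−2.4) adaptors — the signature
that separates the two accounts.

Other subcommands: `simulate` (write a synthetic ratings CSV), `fit` (fit
models to a CSV, `--unconstrained` adds the per-condition GD fits),
`compare` (fit + comparison table). The library API mirrors the CLI; see the
module docstrings in `src/ageadapt/`.

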