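# Methods

## The model

Unmerged, unscaled diffraction data are rows of observed intensities
`I_{h,i}` for Miller index `h` on image `i`, with an integration-reported
uncertainty `sigma_{I_{h,i}}` and a vector of numeric metadata `M_{h,i}`
(detector position, rotation angle, wavelength, Ewald offset,
resolution, ...). The generative model is

    I_{h,i} ~ Likelihood( F_h^2 * Sigma_{h,i} , sigma_{I_{h,i}} )

with two sets of latent variables:

* **Structure factor amplitudes** `F_h`, one per unique reflection
  (per Friedel branch when anomalous merging is on, and per dataset when
  several datasets are merged jointly). The prior is Wilson's
  distribution, with the multiplicity `epsilon_h` and the
  centric/acentric character determined by the space group:

      centric:   p(F) = sqrt(2/(pi*eps)) * exp(-F^2 / (2*eps))
      acentric:  p(F) = (2/eps) * F * exp(-F^2 / eps)

  Both branches satisfy `E[F^2] = epsilon`. The prior is scale-free
  (deliberately independent of `Sigma`), so merged amplitudes come out
  on the Wilson scale; an optional global Wilson B-factor
  (`extract_merged(..., wilson_b=B)`) multiplies `F` and `SigF` by
  `exp(-B/(4 d^2))` for downstream software that expects a resolution
  falloff.

* **Scale factors** `Sigma_{h,i}`, one per observation, produced by a
  learned function of the metadata: a multilayer perceptron
  `f_theta(M) -> (mu_Sigma, sigma_Sigma)` defining a normal surrogate
  `q(Sigma) = Normal(mu_Sigma, sigma_Sigma)`. The prior on scales is
  uninformative (set equal to the surrogate), so its KL term vanishes
  and the scale function is shaped by the likelihood alone.

The likelihood is `Normal(I | F^2 Sigma, sigma_I)` by default, or a
location-scale Student-t with `nu` degrees of freedom
(`LikelihoodConfig("student_t", nu)`) whose heavy tails make the fit
robust to outliers without any rejection step; `nu -> inf` recovers the
normal model. For polychromatic (Laue) data, reflections on one central
ray (integer multiples of a primitive index, within an image) superpose
in a single spot: the likelihood location becomes the sum of `F^2 Sigma`
over the ray's members, with one observed `(I, sigma)` per ray. On
all-singleton partitions this reduces exactly to the monochromatic
likelihood.

## Inference

The amplitude posterior is approximated per reflection by a normal
distribution truncated to the positive half-line, with location and
scale kept positive through a smooth transform (`exp` by default,
`softplus` selectable). The objective is the evidence lower bound

    ELBO = E_q[ log p(I | F, Sigma) ] - KL( q_F || p_Wilson )

estimated by `S` reparameterized Monte-Carlo samples per iteration
(`S = 1` by default; the estimator is written as a mean over samples so
its magnitude does not depend on `S`). Truncated-normal draws use the
inverse-CDF transform `F = loc + scale * ndtri(1 - Phi(loc/scale)(1-u))`,
which is a smooth function of the parameters, so gradients are pathwise.
All gradients come from a small reverse-mode automatic-differentiation
engine on numpy arrays (`varmerge.autodiff`), verified against central
finite differences in the test suite.

Optimization uses Adam with `alpha = 1e-3`, `beta1 = 0.9`,
`beta2 = 0.99`. Two stabilizing choices:

* **Prior-anchored initialization.** The posterior location starts at
  `sqrt(mean observed I)` per reflection (clamped positive at
  `1e-3 x median I`), then the whole vector is rescaled so
  `mean(loc^2/epsilon) = 1`. The joint model is almost exactly invariant
  under scaling all amplitudes up and all scales down (only the prior
  breaks this "gauge"), and that direction is so flat that a fit
  otherwise inherits whatever arbitrary intensity units the data came
  in, biasing every amplitude by a common factor.
* **Polyak averaging.** Trainable parameters are averaged over the last
  25% of iterations (`TrainingConfig.polyak_fraction`, 0 disables).
  With `S = 1` the gradient is noisy at stationarity and Adam iterates
  keep rattling around the optimum; averaging removes that jitter,
  which otherwise inflates point-estimate error beyond the reported
  posterior standard deviation. Deterministic under a fixed seed.

There is no early stopping; the iteration count is user-set (package
default 30,000; the bundled experiments use 4,000-16,000, chosen per
problem size so the smoothed ELBO has plateaued).

## The scale function

Metadata columns are z-scored with training-set statistics
(population SD; constant columns get spread 1), and the stored
`(centers, spreads)` are reused for held-out rows. The MLP has square
hidden layers initialized to identity kernels and zero biases with
leaky-ReLU activations, and a final two-unit linear layer initialized to
zero kernel and bias `(0, s0)` with `constrain(s0) = 1`, so every fit
starts from the metadata-independent scale distribution `Normal(0, 1)`.

Two architecture notes, both documented because the defaults matter:

* **Negative slope 0.3.** With identity kernels, a depth-`L` stack
  multiplies every negative standardized input by `slope^L`. At the
  conventional 0.01 and the default depth 20 this is ~1e-40: half of
  each metadata axis is annihilated and the network cannot represent
  non-monotone scale fields (it demonstrably collapses to a linear
  function of the inputs). A slope of 0.3 keeps signal and gradient
  alive at depth 20.
* **Hidden width.** The default width equals the metadata dimension.
  For low-dimensional metadata (1-3 columns) this is a severe
  expressivity bottleneck — a width-`d` stack reliably converges to a
  linear scale function, and the resulting underfit leaks into the
  amplitudes as a common inflation (the flattened scale estimate makes
  the per-reflection intensity regression compensate upward). Setting
  `ScaleConfig(width=w)` inserts a leading linear projection (tiled
  +/- identity columns, biases spread over [-1, 1] so activation kinks
  start at distinct points). The bundled experiments use widths 8-16.

For serial (still-image) data, `ScaleConfig(n_img_layers=k)` appends
`k` per-image layers between the global stack and the final layer —
identically initialized for every image — so each image learns a local
refinement (e.g. crystal size, partiality trends against the
Ewald-offset metadata) while the global stack captures shared structure.
With a scale function this local, training cannot be minibatched; the
whole dataset is evaluated each iteration.

## Predictions and cross-validation

Predicted intensities use the analytic moments of the surrogates:
`<I> = mu_Sigma (mean_F^2 + var_F)` and
`var(I) = <F^4>(sigma_Sigma^2 + mu_Sigma^2) - <I>^2`, with the
truncated-normal fourth moment from the stable recurrence
`m_k = (k-1) m_{k-2} + alpha^{k-1} phi(alpha)/(1-Phi(alpha))`.

Two validation modes are provided. *Half-dataset*: fit the full data,
freeze the scale-function weights, split images randomly in half, merge
each half separately, and correlate the amplitude estimates per
equal-population resolution bin (default 15 bins) — a CC_1/2 analogue;
with anomalous merging, the correlation of Friedel differences
`F(+) - F(-)` gives CC_anom (Pearson, Spearman, or inverse-variance
weighted). *Hold-out*: train on a retained fraction, predict the
held-out intensities, and report Spearman's rank correlation (robust to
the very outliers one is titrating `nu` against). Held-out rows whose
reflection never appears in training are excluded from the score and
counted in the report, since their posteriors are prior-only.

## The synthetic generators

`make_toy(seed)` is the minimal recovery problem: three acentric P1
reflections with fixed true amplitudes (0.5, 1.0, 1.4) — prior-typical
values, `mean(F^2)` close to the Wilson second moment — observed once
per image over ten images; one rotation-like metadata column `x` with
scale field `exp(1.5 sin(2 pi x))` (a sharp, twenty-fold variation);
Gaussian noise with `sigma = 0.10 (I_true + 0.1 mean I)`. The seed
varies only the noise realization.

`simulate(SyntheticSpec(...))` assembles the full generative model:
amplitudes drawn from the Wilson prior with symmetry-correct
`epsilon`/centricity for the chosen space group (indices sampled within
`|h| <= hmax` on a mock cubic cell, default a = 30 Å, so resolution is
`a/|h|`); a smooth scale field — resolution decay
`exp(-30 s^2)` times `exp(1.2 sin(4 pi phi))` in a rotation-like angle —
optionally times per-image lognormal jitter; Gaussian or Student-t
noise with `sigma_true = noise_level (|I_true| + 0.1)`; reported sigma
equals the true noise scale (a `sigma_misscale` factor stresses that
assumption); outliers add `outlier_scale * sigma * z` to a Binomial
fraction of ray observations. Each reflection is observed at most once
per image.

Laue-style simulation (`harmonic_fraction > 0`) constructs two-member
central rays (a primitive index and its double) sharing one observed
intensity. Identifiability note: the members of a ray share image and
angle, so a scale field over (angle, resolution) alone gives them a
*constant* intensity ratio across all observations and the split is
unidentifiable in principle. What separates harmonics in a real
pink-beam experiment is the spectrum: each member diffracts at
wavelength `lambda/n`. The generator therefore adds a wavelength
metadata column (fundamental `lambda ~ U(1.0, 1.6)`, harmonic
`lambda/2`, singletons `U(0.5, 1.6)`) and multiplies the scale by a
broad spectrum factor `exp(-((lambda - 1.1)/0.4)^2)`.

Change-of-state simulation (`n_datasets = 2`, `changed_fraction`,
`change_scale`) reuses dataset 0's amplitudes and perturbs a random
subset by `±change_scale` fractionally; anomalous signal
(`anomalous_signal`) adds `dF = s * F * z`, `z ~ N(0,1)`, to acentric
Friedel branches.

What the generator does **not** emulate: detector geometry and spot
shapes, correlated (non-diagonal) noise, mis-indexed reflections,
radiation-damage drift within an image series beyond what the smooth
angle term expresses, and integration-stage sigma misestimation (beyond
the optional uniform `sigma_misscale`). Passing recovery tests therefore
demonstrate correctness of the inference given the model's own
assumptions, not performance on any particular real instrument's
systematics.

## Problem sizes in the bundled experiments

The test suite and `scripts/acceptance.py` run scaled-down versions of
each experiment, sized so the whole battery completes on one CPU core in
tens of minutes: the toy (30 rows) over 10-20 noise seeds; standard
recovery with 200 unique reflections at multiplicity 8 (~1,600 rows,
16,000 iterations); the robustness comparison with 100 uniques at
multiplicity 6 over 6-10 paired seeds; harmonic and two-dataset runs
with 200 uniques (~1,600-3,200 rows, 8,000-10,000 iterations). These
sizes are the package's own defaults for demonstration; all scale up
linearly in rows per iteration.

## Known limitations

* Mean-field surrogates ignore posterior correlations between
  amplitudes and the scale function; the common-gauge direction in
  particular is represented only through the prior anchor, so reported
  `SigF` understate uncertainty for very small datasets (visible as
  slightly sub-nominal interval coverage on the toy problem).
* The uninformative scale prior means `sigma_Sigma` is shaped by the
  likelihood only; with very low multiplicity the scale surrogate can
  absorb real amplitude signal (the usual caution against feeding
  intensity-correlated metadata applies).
* Space-group handling covers rotation parts only (sufficient for
  intensities); systematic absences are not deleted, and the ASU
  representative is a package-internal convention (lexicographically
  maximal orbit image), not the CCP4 one.
* Training is full-batch by design; datasets must fit in memory.
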