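# Methods

## The problem and the model

BMI, waist-to-height ratio (WHtR) and waist-to-hip ratio (WHR) grade obesity
from one or two body values and therefore confuse body shape with body fat.
`adiposcan` implements an alternative: grade each of four body regions —
chest, abdomen, hips and the pooled arms/legs — from its full set of
3D-scanner body values (lengths, circumferences, cross-sectional areas,
volumes), then fuse the four regional grades into a single whole-body
obesity class. Ground truth is the DEXA fat percentage: the whole-body class
A/B/C/D (underweight / normal / overweight / obese) is defined by
sex-specific cut points on total tissue fat (men 8 / 18.6 / 23.1 %, women
14 / 22.7 / 27.1 %), and each region's class is defined by the same cut
points applied to that region's tissue fat percentage.

Per region and sex, the model is a principal-component classifier:

1. height-normalize every body value (divide by the subject's stature; the
   model assumes body values scale linearly with stature);
2. z-standardize the variables (they mix ratio scales spanning orders of
   magnitude), form the sample covariance `C = 1/(n-1) Σ (x-x̄)(x-x̄)ᵀ`, and
   eigendecompose it, ordering eigenvalues λ₁ ≥ λ₂ ≥ …;
3. keep the first two components (they carry > 80 % of the variance on data
   with this structure; the retention rule keeps more if the configured
   explained-variance target `fv` is not met by two, but never fewer than
   two, since the classifier lives in the Comp1–Comp2 plane);
4. store every training subject as a labeled point in that plane.

A new subject is projected into each region's plane and assigned the class
of the Euclidean-nearest training point (1-NN; exact ties break to the
higher class). The four regional classes fuse into the whole-body class by:
tabulated exception patterns first (in table order, sex-specific); else
majority (≥ 3 of 4); else a 2–2 tie resolves to the higher class; else the
duplicated class of a 2–1–1 split. The stated rules do not cover an
all-distinct 1–1–1–1 split; we generalize the tie rule — among the
maximal-count classes, the highest wins — which for {A,B,C,D} yields D.
This is deliberate: every stated tie resolution is conservative toward the
higher (riskier) class. The exception table ships as delimited text
(`src/adiposcan/data/exception_rules.csv`), not code, because the published
special-group patterns are explicitly non-exhaustive.

Comparator indices are graded on the same A–D scale with configurable cut
points (defaults: Asian-Pacific BMI bands 18.5/23/25; WHtR 0.40/0.50/0.57;
WHR 0.85/0.90/0.95 men, 0.80/0.85/0.90 women). The published 10-sample
validation table ships as a fixture with each method's class per sample, so
its accuracy row (50 % BMI, 70 % WHtR, 60 % WHR, 80 % proposal) is
recomputed from class matches, never from these index defaults.

## The synthetic cohort generator

The study's human data are not public, so a seeded generator emulates the
cohort: 87 men and 73 women in four strata per sex (men 20/24/23/20,
women 20/20/18/15 across A–D). One latent adiposity factor `a ∈ [0,1]` per
subject drives every fat-linked body value linearly,

    value = intercept(sex) + slope·a + N(0, σ),

while skeletal landmark heights carry zero slope, and stature is a
truncated normal per sex (means 169.15 / 162.8 cm, sd 6 / 5 cm, truncated
to 161–197 / 151–175.7 cm). Regional fat percentages follow the same link
form and are clipped into the stratum's class interval, so stratum labels
are honored by construction. The latent class breakpoints default to the
exact preimages of the fat cut points under each sex's total-fat link
(e.g. men: a = 0.154, 0.562, 0.735), so with zero noise the total fat
percentage is exactly the link value and no clipping occurs.

This generative structure reproduces, rather than assumes, the two
properties the analysis relies on:

* a dominant adiposity component — after height normalization every
  fat-linked column shares the factor `a` and the common 1/stature factor,
  so two components explain well over 80 % of the per-part variance;
* arm–leg coherence — arm and leg circumferences load on the same factor,
  giving pairwise correlations ≥ 0.9, which justifies pooling them into
  one arms/legs dataset.

Noise magnitudes are free parameters (no distributional information beyond
ranges is published); defaults reflect instrument-grade repeatability:
landmark heights ±0.25 cm, circumferences ±0.5–0.8 cm, areas ±4–10 cm²,
volumes ±130–150 cm³, weight ±1 kg, fat percentages ±0.8–1 point.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: multi-factor body-shape variation (only adiposity
and stature vary), allometry (body values here do not co-scale with
stature; stature enters only through the normalization), measurement
artifacts of real scanners (posture, occlusion), and any nonlinearity of
the fat–measurement relationship. Parameter-recovery results on this cohort
are an internal-consistency check of the pipeline, not clinical validation.

The default cohort therefore comprises 160 subjects (87 men + 73 women,
the sum of the stratum table); the separate 10-sample validation table is
not regenerated — it ships as a fixture.

## The vertical-profile module

The scanner-side computation is modeled on 1-D vertical profiles (per
sampled height: total cross-section perimeter and area) rather than meshes,
because the landmark rules are stated purely as patterns in per-height
values. Detection rules and their tunables (`DetectionConfig`):

* neck — first local perimeter minimum scanning down from the crown;
* armpit — first per-slice relative drop > `drop_fraction` (default 15 %)
  below the shoulder maximum;
* navel — interior minimum of the torso band followed by a recovery of at
  least `recovery_fraction` (default 2 %);
* thigh/groin — last sample before the per-slice perimeter jump (same 15 %
  threshold) where the torso splits into two legs;
* knee — centre of the contiguous band, around the rolling-sd maximum
  (window 7 samples), where rolling sd stays above half its maximum.

The published prose for armpit and knee is qualitative ("the last point
before the value disappeared", "periodic variation"); these defaults are
one consistent reading and are flagged as such. Volumes use the trapezoid
rule on the uniform grid — exact for the piecewise-linear template profiles
used in tests; the template generator plants a Gaussian-windowed ripple at
the knee so the variation-band rule has a well-defined truth.

## Numerical choices and edge cases

* Eigendecomposition of the explicitly formed symmetric covariance
  (`scipy.linalg.eigh`), matching the definitional computation; tests
  cross-check against an independent outer-product-sum + general-eigensolver
  oracle to 1e-8. Tiny negative eigenvalues are clipped to zero.
* Loadings are sign-fixed (largest-magnitude element positive) so
  serialized models are bit-reproducible.
* A constant (zero-variance) column raises a degenerate-variance error
  naming the variable — it cannot be standardized and carries no
  information. Height is therefore kept on its raw scale instead of being
  divided by itself.
* Raw-covariance mode (`standardize=False`) is provided because whether the
  original analysis standardized is unstated; the standardized mode is the
  default for the scale-heterogeneity reason above. In the fully
  deterministic limit (zero noise *and* frozen stature) standardization
  amplifies the then-constant skeletal columns, so the exact
  Comp1-orders-adiposity property is checked in raw mode.
* 1-NN distance ties use a relative tolerance of 1e-9 and resolve to the
  higher class, mirroring the fusion tie rule.
* Normalization is enforced exactly-once via a `per_cm` unit tag on the
  measurement map; double normalization is a schema error.
* The held-out evaluation uses a stratified split by (sex, DEXA class) with
  at least one test subject per stratum (default 20 %). The noise-free
  100 %-recovery check is performed in-sample: it is the true deterministic
  limit (each subject's projection coincides with its own training point at
  distance zero). On a held-out split the noise-free limit is *not* exactly
  100 % — a subject with latent adiposity just inside a class cut can have
  its nearest training neighbour across the cut — so the pipeline reports
  both in-sample and held-out accuracy.

## Problem sizes

All simulations use the study-scale cohort (160 subjects) and, where
stability across realizations matters (structural properties, parameter
recovery), five seeded replicates; per-part matrices are at most 87 × 15,
so the full suite and the acceptance script each run in seconds.

## Known limitations

* The per-part accuracy of the 1-NN classifier on synthetic data is
  optimistic relative to real anthropometry (single-factor world; regional
  fat clipped to agree with the whole-body stratum makes part labels
  unusually consistent).
* The published per-part eigenvalue tables and class-summary numbers derive
  from the unreleased human cohort and are not reproducible; only their
  structural shape (eigenvalue shares, per-class component summaries) is
  emitted and property-tested.
* Index cut points for BMI/WHtR/WHR grading were not published; synthetic
  comparator accuracies depend on the documented defaults and are not
  comparable to the published accuracy row, which is reproduced from the
  fixture instead.
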