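# Methods

## The biomarker

Thrombus perviousness describes how much iodinated contrast penetrates an
occlusive clot between CT acquisitions in acute ischemic stroke. The
conventional *standard perviousness* (SP) is the thrombus attenuation
increase (TAI) between non-contrast CT (NCCT) and arterial-phase CT
angiography (CTA): `delta_na = HU_CTA − HU_NCCT`, where each HU value is the
mean clot density over three 1 mm ROIs placed along the clot. *Dynamic
perviousness* adds a late venous phase (CTV) and considers all three
pairwise changes

```
delta_na = CTA − NCCT      (early uptake)
delta_nv = CTV − NCCT      (total uptake)
delta_av = CTV − CTA       (late uptake / washout)
```

with `delta_nv = delta_na + delta_av` holding as an exact identity. The
enhancement curve is classified with a threshold `tau` (default 5 HU) into

| pattern | rule |
| --- | --- |
| `C_NE` no enhancement | `delta_na ≤ tau` and `delta_nv ≤ tau` |
| `C_LE` late enhancement | `delta_na ≤ tau` and `delta_nv > tau` |
| `C_W` early enhancement with washout | `delta_na > tau` and `delta_av ≤ −tau` |
| `C_NW` early enhancement without washout | `delta_na > tau` and `delta_av > −tau` |

**Boundary conventions.** The verbal definitions ("maximum increase of 5
HU", "minimum decrease of 5 HU") overlap at exactly 5 HU. We resolve them as
inclusive on the "maximum/minimum" side: a rise of exactly `tau` is still
"no enhancement", and a fall of exactly `tau` from CTA to CTV is already
washout (`delta_av = −tau → C_W`). With these conventions the four rules are
a true partition of the `(delta_na, delta_av)` plane — every finite input
maps to exactly one category, which the test suite checks on 10^5 random
delta pairs. `C_NE` is defined through the two NCCT-referenced deltas only;
a CTA→CTV rise with both NCCT-referenced deltas ≤ `tau` therefore remains
`C_NE`. Densities are never rounded before threshold comparison, so the
classification is independent of display precision. `tau` is configurable
for sensitivity analyses.

## Statistical models

All categorical fits use treatment coding with `C_NW` as the reference
level. Recanalization success is defined as TICI 2c or 3.

* **Logistic**: success on category indicators, optionally adjusted for clot
  length (mm). Exponentiated coefficients are odds ratios. With no covariate
  the model is saturated, so each OR must equal the closed-form 2×2
  cross-product ratio `(a·d)/(b·c)` against the reference — this closed form
  (with Wald SE `sqrt(1/a+1/b+1/c+1/d)` on the log scale) is kept as an
  independent oracle and the equality is asserted to 1e-6 relative
  tolerance.
* **Continuous-SP logistic**: success on the continuous `delta_na` and
  `delta_nv` (per-HU odds ratios), the comparator analysis for the
  categorical model.
* **Linear**: discharge NIHSS (or 3-month mRS, treated as numeric) on
  category indicators plus the corresponding admission score as baseline
  covariate; complete-case with respect to the outcome and baseline.
* **Poisson**: number of retrieval passes on category indicators, patients
  without an intervention excluded; exponentiated coefficients are rate
  ratios, and the unadjusted model is again saturated (rate ratio = ratio of
  group mean counts, asserted against that oracle).

Confidence intervals and p-values are two-sided Wald on the link scale.
Zero cells in a 2×2 table make the OR degenerate; the closed-form routine
reports this as an explicit error, with an optional Haldane–Anscombe 0.5
correction behind a flag. Complete separation in the logistic fit raises an
error naming the offending category.

## Digital phantoms

A phantom is three co-located HU volumes (NCCT/CTA/CTV) on one axis-aligned
grid (default 0.5 mm isotropic voxels, inside the 0.8 mm clinical quality
bar) containing a cylindrical vessel with an occluding clot segment
(minimum length 3 mm), homogeneous parenchyma, and contrast-opacified
lumen. Gaussian noise of configurable SD is added per phase; zero noise
yields exactly the nominal values, making the measurement round trip exact.
Because all phases share one grid the phantom stands in for perfectly
co-registered clinical series; residual misregistration can be emulated as
an integer-voxel shift of the contrast phases.

Measurement mirrors the clinical procedure: `n = 3` spherical ROIs of 1 mm
diameter are placed at arc fractions `(2k−1)/(2n)` of the clot's physical
extent along its principal axis (so three 1 mm ROIs fit a 3 mm clot exactly,
without overlap), each ROI is averaged per phase over the voxel centres
inside the sphere, and the ROI means are averaged to one density per phase.
Coordinates are physical millimetres with the origin at the volume corner
and voxel centres at `(i + 0.5) · spacing`; ROI membership is
voxel-centre-in-sphere, inclusive.

## Synthetic cohorts

The generator emulates a 137-patient thrombectomy cohort in four groups of
49 (`C_NE`), 22 (`C_NW`), 37 (`C_W`) and 29 (`C_LE`):

* **Densities**: per-group, per-phase independent Gaussians (only marginal
  means/SDs are specified clinically; no covariances are available),
  rejection-sampled until the classification of the draw equals the intended
  group. By construction every stored label agrees exactly with the
  classifier. Conditioning has a visible side effect: the *realised*
  per-group means shift away from the marginal parameters, deeper into each
  category's region of the delta plane (up to ~15 HU for the arterial phase
  of the washout group, whose marginal SD is 31 HU). The realised mean
  triplets still classify into their own categories; matching the marginal
  means exactly would require modelling the latent joint distribution, which
  the available summary statistics do not support.
* **Recanalization**: Bernoulli per group with probabilities 39/49, 15/22,
  29/37, 26/29; TICI grade 3 vs 2c split 70/30 among successes.
* **Passes**: `1 + Poisson(mean − 1)` capped at 9 (observed range 1–9), with
  per-group means 2.5/2.7/2.0/2.6. The cap's effect on the group mean is
  below 1e-3, but the parameter-recovery oracle still computes the exact
  capped mean from the Poisson pmf.
* **Admission NIHSS**: per-group Gaussian (means 13.5/17/12.2/13.6, SDs
  6.9/6.9/6.3/5.5), rounded and clipped to 0–42; the implied overall mean is
  13.7. Because these group distributions are Gaussian while real NIHSS is
  right-skewed, the generator reproduces the group moments but *not* the
  published severity-band proportions (its Gaussian mixture puts ~53% in the
  moderate band versus the reported 41.6%); the severity banding itself
  (0–4 / 5–15 / 16–20 / 21+) is rendered and tested structurally.
* **Discharge NIHSS**: admission − 4 + group effect + N(0, 4), rounded and
  clipped to 0–42. The shift and noise SD were chosen to keep floor-clipping
  mild (a few per cent of draws) so that the baseline-adjusted linear model
  stays close to well-specified and group effects are recoverable; this
  deliberately sacrifices matching the very low observed discharge medians,
  which an additive-Gaussian model cannot reach without heavy censoring.
  Default effects vs `C_NW` are −1.24 (`C_NE`), −1.17 (`C_W`), −3.05
  (`C_LE`).
* **3-month mRS**: admission mRS ~ N(3.5, 1.2) rounded to 0–6, then
  follow-up = admission + 0.4 + group effect + N(0, 1.3), rounded and
  clipped to 0–6. Shift and effects (−0.15/−0.85/−1.30 vs `C_NW`) reproduce
  the observed group means 3.7/3.9/2.9/2.7.
* **Missingness**: 26 deaths before discharge (removing discharge NIHSS
  *and* 3-month mRS), 35 further missing 3-month mRS among survivors, and 10
  patients without intervention (no pass count), all assigned uniformly at
  random. This reproduces the complete-case denominators: 111 at discharge
  and 76 at three months.
* **Covariates**: age, sex (41% female), occlusion site
  (ICA/M1/M2/BA ∝ 43/69/19/6) and clot length (per-group Gaussians clipped
  to the observed 3–61 mm range) are generated for realism and for the
  length-adjusted model.

All draws flow from a single `numpy` generator stream, so cohorts are fully
reproducible from (parameters, seed); `CohortParams.scaled(m)` multiplies
group sizes and missingness totals for recovery studies.

## Verification strategy and problem sizes

Because the patient-level data are not public, the patient-level regression
coefficients are not reproduction targets; the statistical stages are
validated by *parameter recovery* instead. The recovery study uses 200
replicate cohorts at 10× the default size with injected discharge-NIHSS
effects (−1, −1, −3): each stage's replicate estimates must bracket the true
effect within their 2.5–97.5 percentile interval, and the 95% Wald CI for
the late-enhancement odds ratio must cover its true value (computed from the
generating probabilities) in 93–97% of replicates. At the default cohort
size (n = 137) the same coverage lands slightly *above* 97%: roughly 4% of
default-size replicates produce a zero failure cell whose Haldane-corrected
interval is extremely wide, and Wald log-OR intervals are conservative at
cells this small — a known small-sample property, documented here rather
than asserted. Noise-robustness of the phantom measurement is checked over
500 seeded phantoms at 5 HU noise with patterns at least 10 HU from every
decision boundary (misclassification < 5%). These replicate counts keep the
whole suite to well under a minute while leaving Monte-Carlo error far
smaller than the asserted margins.

## Known limitations

* Phase densities are conditionally Gaussian and independent across phases
  within group; real clot densities are spatially structured and correlated
  across phases.
* The phantom has no beam hardening, partial-volume blur or scanner-specific
  texture; noise is white Gaussian.
* Missingness is completely at random, while real deaths and losses to
  follow-up are certainly informative; complete-case estimates on real data
  would carry selection effects the generator does not emulate.
* mRS is modelled and analysed as numeric, matching the reported analysis;
  ordinal models are out of scope.
* Passing the recovery tests demonstrates that the estimation machinery is
  unbiased under the generator's assumptions — not that those assumptions
  hold in any clinical dataset.
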