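# dynaperv

Dynamic perviousness of stroke thrombi on three-phase CT: density
measurement, enhancement-pattern classification, and outcome modelling.

## What this is for

In acute ischemic stroke with large-vessel occlusion, *thrombus
perviousness* — how much iodinated contrast penetrates the clot — is an
imaging biomarker for mechanical thrombectomy planning. Standard
perviousness (SP) uses two time points (non-contrast CT and arterial-phase
CTA) and has shown conflicting predictive value. Adding a late venous phase
(CTV) gives a three-point enhancement curve whose shape — *dynamic
perviousness* — can be classified with a 5 HU threshold `tau` into four
patterns, using `delta_na = CTA − NCCT`, `delta_nv = CTV − NCCT`,
`delta_av = CTV − CTA`:

* `C_NE` — no enhancement: `delta_na ≤ tau`, `delta_nv ≤ tau`
* `C_LE` — late enhancement: `delta_na ≤ tau`, `delta_nv > tau`
* `C_W` — early enhancement with washout: `delta_na > tau`, `delta_av ≤ −tau`
* `C_NW` — early enhancement without washout: `delta_na > tau`, `delta_av > −tau`

The package implements, as tested and reusable components:

* the TAI arithmetic and four-way classifier (also as a scikit-learn
  estimator, `DynamicPerviousnessClassifier`);
* digital three-phase CT phantoms with the three-ROI (1 mm) measurement
  procedure, with NIfTI I/O;
* a synthetic cohort generator reproducing the observed group structure,
  outcome distributions and missingness, for verification without patient
  data;
* the outcome regressions (logistic for recanalization, linear for
  discharge NIHSS / 3-month mRS, Poisson for retrieval passes) with a
  closed-form 2×2 oracle;
* the screening inclusion/exclusion accounting and a reporting pipeline
  with a `dynaperv` command-line interface.

It is aimed at neuroimaging researchers who want to reuse the
classification and analysis chain, or to study its statistical behaviour
under controlled synthetic conditions. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
>>> import dynaperv as dp

>>> deltas = dp.compute_tai((64.4, 74.4, 71.2))   # (NCCT, CTA, CTV) mean HU
>>> deltas
TAIDeltas(delta_na=10.0, delta_nv=6.799999999999997, delta_av=-3.200000000000003)
>>> dp.classify_dynamic(deltas)
'C_NW'

>>> dp.apply_exclusions(475).final                 # screening flow
137

>>> cohort = dp.simulate_cohort(dp.CohortParams(), seed=3)
>>> dp.fit_recanalization_logistic(cohort)[["term", "estimate", "p_value"]].round(3)
   term  estimate  p_value
0  C_LE     4.044    0.067
1  C_NE     2.800    0.093
2   C_W     2.987    0.099
```

The clot in the first example enhances early (`delta_na = 10 > 5`) without
washing out (`delta_av = −3.2 > −5`), so it is `C_NW`. The regression
output reads: in this simulated 137-patient cohort, late-enhancing clots
have about 4× the odds of complete recanalization (TICI 2c/3) compared with
the early-enhancement-no-washout reference, not significant at this sample
size (p = 0.067) — the behaviour the generator is calibrated to produce.

From the shell, the same chain is:

```sh
dynaperv simulate --seed 3 --out cohort.csv
dynaperv classify --in cohort.csv --tau 5 --out classified.csv
dynaperv analyze --cohort classified.csv --models logistic,poisson --out results.csv
dynaperv run --out results/       # whole pipeline, seeded, deterministic
```

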