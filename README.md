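# fibrosurv

Automated quantification of myocardial fibrosis from stained
endomyocardial-biopsy (EMB) images, and evaluation of the fibrosis burden as
a prognostic marker in dilated cardiomyopathy (DCM) — as a tested, fully
synthetic-data-driven pipeline.

In DCM work-ups, left-ventricular EMB fragments (3–5 per patient, 1–2 mm²
each) are stained with Masson's trichrome or AFOG, rendering collagen blue
and cardiomyocytes red/orange.  The **collagen volume fraction**

```
CVF(%) = 100 · total fibrosis area / (total muscle area + total fibrosis area)
```

pooled over all of a patient's fragments (background excluded), summarises
the fibrotic burden.  The quantification chain is: RGB thresholding against
the background mode for region-of-interest detection → pixelwise
classification with a **linear Bayesian classifier** (Gaussian
class-conditionals with shared pooled covariance, i.e. linear discriminant
analysis in colour space, argmax of
δ_k(x) = xᵀΣ⁻¹µ_k − ½µ_kᵀΣ⁻¹µ_k + log π_k) → morphological opening/closing
and small-fragment removal.

The prognostic stage dichotomises CVF at the **minimum-p cutpoint**: 91
log-rank tests at thresholds 5%–95%, smallest p wins.  Around it sit
Kaplan–Meier curves, Cox proportional-hazards model ladders compared by
AIC, restricted-cubic-spline nonlinearity tests, backward elimination
(enter 10% / stay 5%), and bootstrap + predictive-mean-matching multiple
imputation with Rubin pooling.

No patient data ship with the package.  Two first-class generator modules —
synthetic stained slides with planted, exactly known CVF, and synthetic
survival cohorts with a known change-point hazard structure — make every
stage testable against ground truth.  See `docs/methods.md` for the models,
parameters and their rationale.

## Worked example

```python
import fibrosurv as fs

# image stage: plant a fragment with known truth, quantify it blind
slide = fs.generate_fragment(area_mm2=1.5, target_cvf_percent=40.0, seed=7)
slide = fs.add_artifacts(slide, n_dust=5, n_micro_fragments=2, seed=7)
clf = fs.train_classifier(fs.sample_training_pixels(slide, n_per_class=2000, seed=1))
seg = fs.quantify_slide(slide, clf)
cvf = fs.compute_cvf(seg.areas_mm2["fibrosis"], seg.areas_mm2["muscle"])
print(f"planted CVF {slide.true_cvf_percent:.2f}%  measured {cvf:.2f}%")

# survival stage: cohort with a change-point hazard at CVF 32%, HR 3
cohort = fs.simulate_cohort(fs.CohortSpec(n=524, seed=11))
scan = fs.scan_cutpoints(cohort, endpoint="composite")
print(f"optimal cutpoint {scan.optimal_cutpoint}% (log-rank p = {scan.min_p:.2e})")

cohort["cvf_high"] = (cohort["cvf_percent"] > scan.optimal_cutpoint).astype(int)
m = fs.fit_cox(cohort, "time_composite_years", "event_composite",
               ["cvf_high", "log_ntprobnp"])
for name, est in m.terms.items():
    print(f"{name}: HR {est.hr:.2f} "
          f"(95% CI {est.ci95[0]:.2f}-{est.ci95[1]:.2f}), p = {est.p_value:.4g}")
```

prints

```
planted CVF 40.00%  measured 39.98%
optimal cutpoint 32% (log-rank p = 2.94e-06)
cvf_high: HR 3.55 (95% CI 1.93-6.52), p = 4.571e-05
log_ntprobnp: HR 1.28 (95% CI 1.11-1.48), p = 0.0005624
```

The image stage recovers the planted 40% fraction to 0.02 points despite
dust and micro-fragment artifacts; the scan recovers the simulated 32%
change point exactly on this draw, and the Cox model estimates a high-CVF
hazard ratio near the simulated 3 with NT-proBNP (log scale) contributing
independently.

A minimum-p threshold is selected, so its p-value is descriptive only:

```python
fs.minp_null_calibration(n=500, n_sims=200, seed=0)["rejection_fraction"]
# ~0.55 under the null, versus ~0.05 for a fixed single threshold
```

## Command line

```bash
fibrosurv synth-slides --n 10 --area 1.5 --cvf 30 --seed 1 --out slides/
fibrosurv quantify     --slides slides/ --out cvf.csv
fibrosurv synth-cohort --n 524 --seed 2 --out cohort.csv
fibrosurv cutpoint     --cohort cohort.csv --endpoint composite --out scan.json
fibrosurv analyze      --cohort cohort.csv --endpoint composite --seed 3 --out results/
fibrosurv run          --config run.yaml    # full pipeline with manifest
```

`fibrosurv run` drives slides → per-patient CVF → cohort merge → cutpoint
scan → group comparisons → model ladder → Kaplan–Meier figures from one
YAML config in which every stochastic stage has an explicit seed; reruns
are numerically identical and a manifest records SHA-256 hashes of every
output.

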