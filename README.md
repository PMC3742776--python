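# mirapanel

Does a panel of circulating microRNAs add real prognostic value to a
clinical model of left-ventricular (LV) contractility after acute
myocardial infarction (AMI)?  `mirapanel` implements the complete
statistical workflow for answering that question — for biostatisticians and
cardiovascular researchers who want the whole chain (model fitting, panel
selection, reclassification, internal validation) reproducible from a single
seed.

## The problem and the models

After AMI, LV contractility at follow-up is summarised by the wall motion
index score (WMIS): the mean of per-segment scores (0 hyperkinetic, 1
normal, 2 hypokinetic, 3 akinetic, 4 dyskinetic) over up to 16
echocardiographic segments.  WMIS = 1 means fully preserved contractility —
in a typical cohort more than a third of patients sit exactly at this floor
— and WMIS > 1.2 (≈ ejection fraction < 40%) defines impairment.

Two model families predict follow-up WMIS from clinical covariates (age,
sex, risk factors, infarct type and territory), log₁₀ Nt-proBNP and
spike-in-normalised miRNA levels (`2^(mean spike Ct − target Ct)`, log₂ in
the models):

* **Logistic regression** for the dichotomised outcome
  `P(WMIS > 1.2 | x) = expit(xᵝ)`, with Wald tests and odds ratios
  `exp(β)`; patients classify as impaired when the fitted probability
  is ≥ 0.5.
* **Left-censored (tobit) regression** for the continuous score: latent
  `WMIS* = xᵝ + ε`, `ε ~ N(0, σ²)`, observed at `max(WMIS*, 1)`.  The
  log-likelihood combines `log φ((yᵢ − xᵢβ)/σ) − log σ` for uncensored
  observations with `log Φ((1 − xᵢβ)/σ)` for patients at the floor; per-term
  Z tests replace the Wald chi-squares.

Around these sit the added-value machinery:

* exhaustive search over all `2^m − 1` marker combinations, scored by global
  Wald p, **AIC** (= 2k − 2·loglik) and the likelihood-ratio test against
  the clinical base model; the AIC minimiser (the base model included) wins;
* **continuous NRI** (net fraction of events whose risk rises plus net
  fraction of nonevents whose risk falls; range [−2, 2]) and **IDI** (change
  in discrimination slope), with large-sample nullity tests;
* **bootstrap optimism correction** that repeats the *entire* AIC selection
  inside each of B = 150 resamples, measures train-minus-test performance,
  and subtracts the average from the apparent value — plus per-subset
  selection frequencies;
* **borderline-patient LOOCV**: patients with 1 < WMIS < 1.4 are omitted
  one at a time, refitted, and classified; sensitivity/specificity/PPV/NPV
  are compared between the base and base+panel models.

A calibrated synthetic-cohort generator (latent-tobit structure, realistic
covariate prevalences, fixed effect directions) makes every stage testable
without patient data.

## Worked example

```bash
mirapanel report --seed 7 --out-dir out/
```

runs the full pipeline on a simulated 150-patient cohort and prints:

```
[logistic] best subset (full sample): mir_16+mir_27a+mir_101+mir_150; NRI apparent=1.412 corrected=1.265
[tobit] best subset (full sample): mir_16+mir_27a+mir_101+mir_150; NRI apparent=1.305 corrected=1.253
borderline: base sens=0.57 spec=0.56 -> panel sens=0.52 spec=0.61
```

Reading this: on this cohort the exhaustive AIC search selects the full
4-miRNA panel under both families (its logistic AIC drops from 192.931 for
the clinical model to 106.463 with the panel).  The apparent continuous NRI
of 1.41 shrinks to 1.27 after subtracting the bootstrap optimism of 0.15 —
the panel's added discrimination survives internal validation, and the full
panel was re-selected in 93% of the 150 resamples (see
`out/validation.json`).  Among the 39 borderline patients the panel trades
a little sensitivity for specificity on this particular draw.  All eight
artifacts in `out/` (`config.yaml`, `cohort.csv`, `models.json`,
`selection_*.tsv`, `reclassification.tsv`, `validation.json`,
`borderline.json`) embed the seed and config hash and are byte-identical
across reruns.

The same stages are available individually (`simulate`, `fit`, `select`,
`reclassify`, `validate`, `borderline`) and as library calls
(`Logistic(X, y).fit()`, `Tobit(X, y).fit()`, `added_value_table`,
`compare_models`, `bootstrap_validate`, `borderline_eval`).

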