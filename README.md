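# fltpet

Early radiotherapy-response analysis of [18F]fluorothymidine (FLT) PET in
non-small cell lung cancer (NSCLC), as a tested, reusable Python library.

FLT uptake tracks thymidine kinase 1 activity and hence tumour
proliferation, making it a candidate early pharmacodynamic readout of
radiotherapy (RT) response. The analytical chain this package implements
answers the question *"did this lesion's uptake change more than
measurement noise, and do primary tumours and nodal metastases respond
differently?"*:

- **SUV quantification** — activity images (kBq/ml) to standardized uptake
  value maps, SUV = A · weight/dose, with F-18 decay correction, 4-mm
  Gaussian smoothing, VOI statistics (volume, SUV_mean, SUV_max) and a
  bone-marrow-overlap QC check.
- **Test-retest repeatability** — duplicate-baseline differences
  (S2 − S1)/(S1 + S2) × 200, their SD, and the repeatability coefficient
  RC = 1.96 × SD, the change threshold attributable to noise.
- **Response & BED** — (S3 − baseline)/baseline × 100 against the latest
  baseline, and the biologically effective dose n·D·(1 + D/(α/β)) of the
  fractionation delivered before the response scan.
- **Mixed-effects offset ANCOVA** (the core) — on the log10 scale,
  log10(y1) = log10(y0) + (β0 + b_i) + β1·[node] + ε, with patient random
  intercept b_i ~ N(0, σ_b²); fitted by profile maximum likelihood, with
  AIC, back-transformed percent effects 10^β − 1 with 95% CIs, the
  variance partition σ_b²/(σ_b² + σ²), and an optional BED covariate.
- **Rank statistics** — self-contained Spearman and Wilcoxon rank-sum
  tests with tie handling and exact small-sample p-values.
- **Outcome** — Kaplan-Meier curves with median survival and univariate
  Cox regression on continuous PET parameters.
- **Synthetic data** — a cohort generator realizing exactly this model
  (plus digital phantoms and survival simulation), so the full pipeline is
  testable end-to-end without patient data.

## Worked example

```python
from fltpet import fit_ancova, generate_cohort, reference_cohort_config
from fltpet.pipeline import model_input_from_cohort

cohort = generate_cohort(reference_cohort_config(seed=11))   # 12 patients
y0, y1, pats, nodes, _ = model_input_from_cohort(cohort, "suv_mean", model="B")
fit = fit_ancova(y0, y1, pats, nodes)
print(fit.effect_primary_pct, fit.effect_node_pct, fit.variance_partition)
```

Running `python examples/04_response_mixed_model.py` prints (among other
lines):

```
suv_mean: primary -21.4% (CI -30.4 to -11.3), node -37.8%, patient share of variance 28.4%, AIC -53.1
```

Read: on this simulated 12-patient cohort (generated at the published
effect sizes of −25% for primaries and −40% for nodes), the model estimates
that one week of RT reduced primary-tumour SUV_mean by 21% and nodal
SUV_mean by 38%, and that 28% of the residual spread in responses is
patient-level heterogeneity rather than lesion-to-lesion variation — all
within sampling error of the generating truth at this cohort size.

The other scripts in `examples/` demonstrate cohort generation, phantom
quantification with bone QC, the repeatability coefficients, and KM/Cox
outcome analysis; each prints the numbers it computes with a note on their
meaning.

A thin CLI mirrors the library:

```bash
flt simulate --seed 1 --out cohort.csv
flt repro    --cohort cohort.csv --out repro.json
flt fit      --cohort cohort.csv --model B --parameter suv_mean
flt demo     --seed 1 --out demo.json
```

## Layout

```
src/fltpet/        synthetic, suv, reproducibility, response,
                   mixed_model, stats, outcome, pipeline, cli, presets
examples/          one narrative script per capability
tests/             unit, property and acceptance suites
docs/methods.md    model, assumptions, numerical choices, limitations
```
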