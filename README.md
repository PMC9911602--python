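# phytossd

Species sensitivity distributions (SSDs) for setting **generic phytosanitary
irradiation doses** — single treatment schedules accepted as efficacious for
an entire insect taxon (a genus, family or order) rather than one tested
species.

Regulators approving a generic dose need to know what fraction of a taxon
the dose can be expected to control, and with what uncertainty. This package
answers that by borrowing the SSD framework from ecotoxicology: treat the
per-species minimum effective dose as a draw from a parametric distribution,
fit it to a literature review table, and read decision quantities off the
fitted curve:

* **GD_p** — the generic dose at coverage `p`: the dose at which the fitted
  CDF reaches `p` (the mirror image of ecotoxicology's HC_5);
* **coverage** — `100 × CDF(dose)`, the estimated percent of species in the
  taxon controlled at a candidate dose, with parametric-bootstrap confidence
  intervals.

It is aimed at phytosanitary treatment researchers and risk analysts working
with irradiation dose literature (doses in gray, Gy).

## What it does

* **Dose-table ingestion and combination** — reads CSV tables of literature
  records (species, dose, specimens treated, highest failing dose); merges
  multiple records per species by a geometric mean weighted by each record's
  *efficacy confidence* `C = 1 − e^n` (the probability a zero-survivor study
  of `n` insects would have caught a sub-target efficacy `e`).
* **Outlier screening** — Cook's distance from `dose ~ n + F`, removing
  arbitrarily high doses reported without supporting low-dose testing.
* **Parametric SSD fitting** — log-normal, log-logistic, gamma and Weibull
  by maximum likelihood, for exact doses or interval-censored doses; family
  selection by AICc.
* **Balanced interval censoring** — encodes study quality as per-species
  dose intervals `[L, D + A(1 − C)]` whose mean upper gap equals the mean
  lower gap exactly, widening weak studies without shifting the dataset.
* **Inference** — GD_p, coverage, percentile parametric-bootstrap CIs
  (5,000 iterations by default, bit-reproducible under a seed), and the
  marginal-gain dose beyond which coverage grows slower than `m` %/Gy.
* **Cox–Snell small-sample bias correction** of the gamma fit, in closed
  form.
* **Synthetic literatures** — a generator that simulates dose-grid studies
  with binomial survival under a probit dose-response, for validating the
  whole pipeline against known ground truth.

Two literature tables ship as fixtures: a 31-record Curculionidae (weevil
and bark beetle) review and a 15-species Tephritidae (fruit fly) table of
combined sterilizing doses.

## Worked example

```python
import phytossd as p

doses = [r.dose_gy for r in p.load_tephritidae()]   # 15 combined species doses
ssd = p.ParametricSSD(family="gamma").fit(doses)

print(f"shape = {ssd.params_['shape']:.3f}, scale = {ssd.params_['scale']:.2f}")
print(f"AICc  = {ssd.aicc_:.2f}")
for prob in (0.90, 0.95, 0.99):
    print(f"GD{int(prob*100)}  = {ssd.quantile(prob):6.2f} Gy")
print(f"coverage at 150 Gy = {100*ssd.cdf(150):.1f} %")

est = p.bootstrap_ci(ssd.result_, "gd_at_p", 0.95, n_boot=5000, seed=1)
print(f"GD95 90% CI = ({est.ci_low:.1f}, {est.ci_high:.1f}) Gy")
```

prints

```
shape = 3.427, scale = 20.88
AICc  = 154.07
GD90  = 123.40 Gy
GD95  = 144.65 Gy
GD99  = 190.40 Gy
coverage at 150 Gy = 95.8 %
GD95 90% CI = (105.2, 182.9) Gy
```

Reading: under the fitted gamma SSD, a 123 Gy generic dose is expected to
control 90% of Tephritidae species, and the approved-style 150 Gy schedule
covers about 96% of the family; the bootstrap interval spells out how loose
a 15-species estimate still is. `ParametricSSD(family="auto")` fits all
four families and keeps the lowest-AICc one; `p.coxsnell_correct_gamma`
then quantifies how much of the dose requirement is small-sample bias
(here the corrected GD95 is 11.8 Gy lower).

The same pipeline runs from the shell:

```sh
phytossd report table.csv --family auto --gd 0.90,0.95,0.99 \
    --at-dose 150,175 --boot 5000 --seed 1 --out report.json
phytossd simulate --species 30 --n-per-dose 12 --seed 7 --out sim.csv
```

`report` writes a JSON run report (dataset summary, screening decisions,
per-family fit table, estimates with CIs) plus an optional dose/coverage
curve CSV for replotting; `simulate` writes a synthetic literature directly
consumable by `fit`/`report`.

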