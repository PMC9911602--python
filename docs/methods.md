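# Methods

## The model

A species sensitivity distribution (SSD) treats the irradiation dose a
species requires for phytosanitary control as a random draw from a positive
continuous distribution over the taxon. Fitting that distribution to a
literature table of per-species minimum effective doses yields two decision
quantities:

* **GD_p**, the generic dose at coverage `p`: the dose at which the fitted
  cumulative distribution reaches `p`, i.e. the dose expected to control a
  fraction `p` of the taxon (the phytosanitary mirror image of
  ecotoxicology's hazardous concentration HC_5);
* **coverage at a dose**: 100 x the fitted CDF at a candidate generic dose.

Four two-parameter families are supported, all with support on `x > 0`:

| family | parameters | CDF |
|---|---|---|
| gamma | shape `a`, scale `s` | regularized lower incomplete gamma |
| log-normal | meanlog `mu`, sdlog `sigma` | `Phi((ln x - mu)/sigma)` |
| log-logistic | shape `b`, scale `s` | `1 / (1 + (x/s)^-b)` |
| Weibull | shape `k`, scale `s` | `1 - exp(-(x/s)^k)` |

These map onto `scipy.stats` as `gamma`, `lognorm(s=sigma,
scale=exp(mu))`, `fisk`, and `weibull_min`. The family is chosen by the
smallest AICc, `AIC + 2k(k+1)/(n-k-1)` with `k = 2`; exact ties resolve in
the fixed order gamma, log-normal, log-logistic, Weibull so reruns are
deterministic. Model choice is by information criterion only; an
Anderson–Darling statistic is available as a diagnostic for exact data but
plays no role in selection.

Key assumptions worth keeping in mind: the species in the table are an
unbiased sample of the taxon (in reality they skew toward economically
important, rearable species); the reported endpoints are comparable across
studies; and a two-parameter family is flexible enough for the taxon.

## Efficacy confidence and dose combination

A study that treats `n` insects at a dose with zero survivors supports the
claim of a target efficacy `e` (default 0.9999, the probit-8.72 convention)
with confidence

    C = 1 - e^n,

the probability that at least one survivor would have appeared if the
per-insect kill probability were exactly `e`. This reading — the printed
formula's `p` as the per-insect *survival* proportion — is the only one
consistent with the standard benchmarks it is used against (93,613 insects
at probit-9 efficacy giving 95% confidence; a 12-insect study at 84.13%
efficacy passing with probability `0.8413^12 ~ 12.6%`).

When several studies report doses for one species they are merged into a
single SSD datum by the confidence-weighted geometric mean
`exp(sum(C_i ln D_i) / sum(C_i))`, except that when any record's confidence
exceeds the retention threshold (default 0.9999) the lowest such
near-conclusive dose is retained outright. Records without a specimen count
carry no weight; a species with only such records falls back to the
unweighted geometric mean with a warning.

## Outlier screening

Reported doses are regressed (OLS, via statsmodels) on study-quality
covariates — the specimen count `n` and the highest tested dose with
observed failure `F` — and observations with Cook's distance above a
threshold are removed before the crude fit. Two thresholds are offered:
4 x the mean distance (default) and `4/n`. A covariate missing from every
record is dropped from the design, so a table without `F` is screened
against `dose ~ n` alone; records missing a retained covariate pass through
unscreened. A design whose residual mean square is at rounding level
(relative tolerance 1e-20 of the mean squared response) is treated as an
exact fit with all distances zero. One pass only; no iterative re-screening.

## Interval censoring for heterogeneous study quality

Each reported dose `D` becomes an interval `[L, U]`: `L` is the highest
dose with observed treatment failure, floored at 25 Gy (the lowest
effective dose on record, applied as `max(L, 25)` and never above `D`),
and `U = D + A(1 - C)` with the spread factor `A = u_l / (1 - u_c)` built
from the dataset means `u_l = mean(D - L)` and `u_c = mean(C)`. The
construction is *balanced* by algebra, not by tuning:
`mean(U - D) = A(1 - u_c) = u_l = mean(D - L)` exactly, which the test
suite checks to machine precision on random datasets. `u_c = 1` leaves `A`
undefined and is rejected with advice to fit the exact doses; doses without
a confidence are excluded with a warning.

When per-species lower bounds are unavailable (the packaged Curculionidae
table carries none), every `L` is the 25 Gy floor; the censored analysis is
then exercised as a directional tool — on simulated mixed-quality
literatures it yields a steeper fitted SSD and higher coverage near the
crude GD95 than the exact-dose fit, which the tests assert.

## Maximum likelihood

Exact doses contribute log densities; an interval contributes
`log(F(U) - F(L))`, with degenerate intervals falling back to the density so
that censored fitting on `[x, x]` reproduces the exact fit (asserted to
1e-6 in parameters for all four families). Zero-probability intervals
contribute `-inf` rather than raising.

Exact-data fits avoid generic optimization where possible: the log-normal
MLE is closed form (mean and uncorrected SD of logs); the gamma shape
solves `ln a - psi(a) = ln(mean) - mean(ln x)` by Newton from the standard
rational first guess (relative tolerance 1e-13); the Weibull shape is a
bracketed Brent root of the profile score (xtol 1e-12) with the scale
profiled out; the log-logistic uses Nelder–Mead on log-parameters
(xatol 1e-10, fatol 1e-12) started from logistic moment matching on logs.
Censored fits use Nelder–Mead on log-parameters started from the exact-data
estimates on interval midpoints. Everything is deterministic — fixed
starting values, no randomness — and non-convergence flags the fit as
unusable for selection rather than raising mid-pipeline.

## Bootstrap uncertainty

Confidence intervals are percentile parametric bootstrap: draw `n_obs`
doses from the fitted distribution, refit the same family, recompute the
statistic, repeat (default 5,000 replicates), and take the percentile
interval (default 90%). Replicate substreams are spawned deterministically
from one root seed, so results are bit-reproducible for a fixed
`(seed, n_boot, data)` and independent of execution order. For censored
fits the replicates are exact draws refitted as exact data: the censoring
describes the quality of the observed studies, not the sampling model of
the fitted distribution. Gamma replicates run through a vectorized Newton
refit; other families loop through the standard fitting path, with
non-converged replicates dropped and counted (flagged above 10%).

The percentile method is deliberately the simplest choice (no BCa). Its
known cost is visible in this package's own coverage study (500 simulated
n=15 gamma literatures, 500 replicates each, in the acceptance tests): the
90% interval for GD95 covers the true quantile in roughly 82–85% of runs at
n = 15, climbing to ~91% by n = 60. Small-sample intervals should be read
as approximate.

## Cox–Snell bias correction (gamma)

The gamma MLE is biased at small n. The first-order (Cox–Snell) bias in the
shape/scale parameterization has the closed form

    b(a) = (-a^2 psi''(a) + a psi'(a) - 2) / (2 n (a psi'(a) - 1)^2)
    b(s) = s (a psi''(a) + psi'(a))        / (2 n (a psi'(a) - 1)^2)

and the corrected estimate is `MLE - b`. The expressions were derived from
the expected second- and third-order log-likelihood derivatives; the
internal machinery is the generic Cordeiro–Klein matrix construction over
per-observation cumulants (so further families can be added), and the
closed form is cross-checked against it and against a parametric-bootstrap
bias oracle in the tests. Only the gamma — the family for which the
correction is practically needed — is exposed. Corrected parameters are
plugged into the standard gamma quantile/CDF to report corrected GD_p and
coverage. Two caveats: the correction is not equivariant under
reparameterization (correcting shape/rate gives a different distribution;
this package fixes shape/scale, matching how results are reported), and at
n = 15 the neglected O(1/n^2) remainder is visible — the empirical shape
bias exceeds the first-order term by roughly a quarter — so the correction
removes most, not all, of the bias. A correction that would drive a
parameter non-positive raises instead of returning nonsense.

## Marginal-gain (slope) dose

Beyond the density mode, coverage gained per extra gray — `100 f(x)` in
percentage points per Gy — declines monotonically. The slope criterion dose
for a rate `m` is the smallest dose at or above the mode with
`100 f(x) < m`, found by doubling-bracket plus Brent root (xtol 1e-10); if
even the peak density is below `m` the mode itself is returned.

## Synthetic literatures

The generator emulates how the real tables arise. Species tolerances are
i.i.d. draws from a chosen SSD, where a species' "tolerance" is its
ED_target (dose achieving the target efficacy, default 99.99%) — the same
quantity the literature doses estimate. Per-insect kill probability is
probit in log10 dose, `Phi(Phi^{-1}(e_t) + slope (log10 d - log10 tol))`,
anchored so the tolerance achieves the target exactly. Each study treats
`n_per_dose` insects at every grid dose; survivors are binomial; the study
publishes the lowest grid dose from which upward no survivor appeared, the
count treated there, and the highest failing dose.

Defaults mirror the study designs behind the packaged tables: a 25–400 Gy
grid in 25 Gy steps, 12 insects per dose (the small wood-borer studies),
probit slope 5 per log10 Gy (a mid-range insect dose-response steepness),
target efficacy 0.9999. A tuple-valued `n_per_dose` cycles across species
to emulate mixed-quality literatures.

The generator reproduces the two data-quality pathologies that motivate the
censored analysis, and the tests assert both directions: sparse designs
(12 insects) let under-dosed studies pass by chance, dragging reported
doses below the truth and inflating the fitted spread; heavily replicated
confirmatory designs can only report doses at which zero survivors among
tens of thousands is plausible, pushing reported doses conservatively above
the ED_target. What it does not emulate: heterogeneous endpoints across
studies, publication bias beyond the design effects, dose-uniformity spread
within a treatment, or any taxonomic correlation structure among species.
Passing recovery tests therefore validate the pipeline's statistics under
the stated sampling model, not the biases of any particular real
literature.

## Problem sizes and determinism

Default analyses: 5,000 bootstrap replicates at 90% level. The test suite
runs its simulation oracles at sizes chosen to keep Monte-Carlo error well
inside the asserted tolerances: 2,000 replicates for the n=15 bias oracle,
40,000 for the n=150 check, 500 x 500 for the bootstrap coverage study,
10,000 draws for distributional checks. All randomness flows from explicit
seeds (numpy `default_rng`, spawned substreams); reruns are reproducible
bit for bit.

## Known limitations

* The packaged Curculionidae table lacks per-study failing doses, so its
  censored analysis floors every lower bound at 25 Gy; supply
  `highest_fail_dose_gy` to sharpen it.
* Percentile bootstrap intervals undercover at n ~ 15 (above).
* The bias correction is gamma-only and first-order.
* No model averaging across families; selection is winner-take-all by AICc,
  and at n ~ 15 the AICc differences between families are typically small.
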