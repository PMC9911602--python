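"""Synthetic species-tolerance datasets and simulated dose-finding studies.

The literature tables behind an SSD are the end product of a particular study
design: a species with some true radiotolerance is treated at a grid of
doses, a fixed number of insects per dose, and the study reports the lowest
grid dose at which no insect survived (produced viable offspring). This
module generates data with exactly that structure so the whole pipeline —
combination, screening, fitting, censoring, inference — can be exercised
against a known ground truth.

The generating model:

* per-species true tolerances are i.i.d. draws from a parametric SSD
  (the "tolerance" of a species is its ED_target, the dose achieving the
  target efficacy — by default 99.99%, the probit-8.72 convention — so the
  generating SSD is the distribution the literature doses estimate);
* the per-insect kill probability follows a probit model in log10 dose with
  a configurable slope, anchored so that ``kill(tolerance) = target``;
* at each grid dose the number of survivors is binomial; the reported
  minimum effective dose is the lowest grid dose from which upward no
  survivor was observed, and the highest failing dose becomes the record's
  lower-bound information.

The no-survivor calculus lives here too: with per-insect efficacy ``e`` and
``n`` treated insects, the chance of observing zero survivors is ``e**n`` —
at probit-6 efficacy (84.13%) a 12-insect study passes with probability
~12.5%, which is how under-powered studies come to report doses far below a
species' true requirement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .records import DoseRecord
from .distributions import DistributionSpec, ssd_quantile

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "prob_no_survivors",
    "kill_probability",
    "simulate_tolerances",
    "simulate_study",
    "simulate_dataset",
    "end_to_end_recovery",
]

#: default probit-model slope, probits per log10 gray
DEFAULT_SLOPE = 5.0


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated dose-finding literature.

    ``tolerance_spec`` is the generating SSD of per-species ED_target values.
    ``dose_grid`` (strictly increasing, Gy) and ``n_per_dose`` describe each
    study; ``response_slope`` is the probit slope of the per-insect
    dose-response in probits per log10 Gy (steep = sharply thresholded
    mortality). ``target_efficacy`` anchors what "tolerance" means.
    """

    tolerance_spec: DistributionSpec
    n_species: int = 30
    dose_grid: tuple[float, ...] = tuple(float(d) for d in range(25, 401, 25))
    n_per_dose: int | tuple[int, ...] = 12
    response_slope: float = DEFAULT_SLOPE
    target_efficacy: float = 0.9999
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = tuple(float(d) for d in self.dose_grid)
        if len(grid) < 1 or any(d <= 0 for d in grid):
            raise ValueError("dose_grid must contain positive doses")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("dose_grid must be strictly increasing")
        object.__setattr__(self, "dose_grid", grid)
        if not isinstance(self.n_per_dose, int):
            object.__setattr__(self, "n_per_dose", tuple(int(n) for n in self.n_per_dose))
        ns = (self.n_per_dose,) if isinstance(self.n_per_dose, int) else self.n_per_dose
        if len(ns) < 1 or any(n < 1 for n in ns):
            raise ValueError("n_per_dose must be >= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 < self.target_efficacy < 1.0:
            raise ValueError("target_efficacy must lie in (0, 1)")
        if not self.response_slope > 0:
            raise ValueError("response_slope must be > 0")


@dataclass(frozen=True)
class SimulatedStudy:
    """One simulated dose-finding study and the record it would publish."""

    species_id: str
    true_tolerance_gy: float
    survivors: tuple[int, ...]  # per grid dose
    record: DoseRecord | None  # None when no grid dose achieved zero survivors


def prob_no_survivors(efficacy: float, n: int) -> float:
    """Probability that ``n`` treated insects yield zero survivors.

    Independent per-insect survival: ``efficacy ** n``. Equals
    ``1 - confidence_of_efficacy(n, efficacy)`` by construction.
    """
    if not 0.0 <= efficacy <= 1.0:
        raise ValueError("efficacy must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 1.0
    if efficacy == 0.0:
        return 0.0
    return math.exp(n * math.log(efficacy))


def kill_probability(
    dose,
    tolerance_gy: float,
    slope: float = DEFAULT_SLOPE,
    target_efficacy: float = 0.9999,
):
    """Per-insect kill probability under the probit log-dose model.

    ``Phi(z_t + slope * (log10(dose) - log10(tolerance)))`` with
    ``z_t = Phi^{-1}(target_efficacy)``, so a dose equal to the species'
    tolerance kills exactly the target fraction.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0) or tolerance_gy <= 0:
        raise ValueError("doses and tolerance must be > 0")
    z = stats.norm.ppf(target_efficacy) + slope * (np.log10(dose) - math.log10(tolerance_gy))
    out = stats.norm.cdf(z)
    return float(out) if out.ndim == 0 else out


def simulate_tolerances(
    spec: DistributionSpec, n_species: int, seed
) -> np.ndarray:
    """I.i.d. species tolerances from the generating SSD (seed-reproducible)."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return spec.frozen.rvs(size=n_species, random_state=rng)


def simulate_study(
    true_tolerance_gy: float,
    config: SimConfig,
    rng: np.random.Generator,
    species_id: str = "sp",
) -> SimulatedStudy:
    """Simulate one dose-grid study for a species of known tolerance.

    Survivors at each grid dose are binomial with the probit kill
    probability. The published record reports the lowest grid dose from
    which upward every tested dose had zero survivors (the literature's
    "minimum effective dose"), the specimen count at that dose, and the
    highest failing dose as lower-bound information. When even the top grid
    dose left survivors the study reports nothing (``record=None``).
    """
    if not isinstance(config.n_per_dose, int):
        raise ValueError(
            "simulate_study needs a single n_per_dose; simulate_dataset "
            "handles per-study lists"
        )
    kill = kill_probability(
        np.array(config.dose_grid), true_tolerance_gy,
        config.response_slope, config.target_efficacy,
    )
    survivors = rng.binomial(config.n_per_dose, 1.0 - kill)
    record = None
    fail_idx = np.flatnonzero(survivors > 0)
    first_clean = int(fail_idx[-1]) + 1 if fail_idx.size else 0
    if first_clean < len(config.dose_grid):
        highest_fail = (
            float(config.dose_grid[first_clean - 1]) if first_clean > 0 else None
        )
        record = DoseRecord(
            species=species_id,
            family="Simulated",
            dose_gy=float(config.dose_grid[first_clean]),
            n_treated=config.n_per_dose,
            highest_fail_dose_gy=highest_fail,
            source="simulation",
        )
    return SimulatedStudy(
        species_id=species_id,
        true_tolerance_gy=float(true_tolerance_gy),
        survivors=tuple(int(s) for s in survivors),
        record=record,
    )


def simulate_dataset(config: SimConfig) -> list[SimulatedStudy]:
    """Simulate one study per species under a shared root seed.

    A tuple-valued ``n_per_dose`` is cycled across species, emulating a
    literature of heterogeneous study sizes.
    """
    from dataclasses import replace

    rng = np.random.default_rng(config.seed)
    tolerances = simulate_tolerances(config.tolerance_spec, config.n_species, rng)
    ns = (
        (config.n_per_dose,) if isinstance(config.n_per_dose, int) else config.n_per_dose
    )
    return [
        simulate_study(
            tol,
            replace(config, n_per_dose=int(ns[i % len(ns)])),
            rng,
            species_id=f"sp{i:04d}",
        )
        for i, tol in enumerate(tolerances)
    ]


def end_to_end_recovery(
    config: SimConfig,
    seeds: Sequence[int],
    p: float = 0.95,
    family: str = "auto",
) -> dict:
    """Run the full pipeline on simulated literatures and score GD_p recovery.

    For each seed: simulate studies, keep the published records, screen,
    combine (one record per species here), fit, and read off GD_p. Reports
    per-seed estimates plus bias and RMSE against the generating
    distribution's true quantile, and the mean fraction of species whose
    studies reported nothing.
    """
    import warnings

    from .distributions import ParametricSSD
    from .records import combine_all
    from .screening import screen_outliers

    true_q = ssd_quantile(config.tolerance_spec, p)
    estimates, missing_frac = [], []
    for seed in seeds:
        cfg = SimConfig(**{**config.__dict__, "seed": int(seed)})
        studies = simulate_dataset(cfg)
        records = [s.record for s in studies if s.record is not None]
        missing_frac.append(1.0 - len(records) / len(studies))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept = screen_outliers(records).kept
            doses = [d.dose_gy for d in combine_all(kept)]
            ssd = ParametricSSD(family=family).fit(doses)
        estimates.append(float(ssd.quantile(p)))
    est = np.array(estimates)
    return {
        "p": p,
        "true_quantile_gy": float(true_q),
        "estimates_gy": estimates,
        "bias_gy": float(est.mean() - true_q),
        "relative_bias": float((est.mean() - true_q) / true_q),
        "rmse_gy": float(np.sqrt(np.mean((est - true_q) ** 2))),
        "mean_unreported_fraction": float(np.mean(missing_frac)),
    }
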