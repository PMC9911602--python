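"""End-to-end pipeline: read -> combine -> screen -> [censor] -> fit ->
inference -> [bias-correct] -> machine-readable report.

The run report is a plain JSON-serializable dictionary that echoes its
configuration, so a report plus the input CSV reproduces the run exactly
(given the same seed). Reruns with identical config are numerically
identical apart from timestamps.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .bias_correction import corrected_shift, coxsnell_correct_gamma
from .censoring import build_balanced_intervals
from .distributions import FAMILIES, fit_all, ssd_cdf
from .inference import bootstrap_ci
from .records import (
    DoseRecord,
    EfficacyPolicy,
    combine_all,
    read_dose_table,
)
from .screening import screen_outliers

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "coverage_curve"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    input_path: str | None = None  # None when records are passed directly
    taxon: str = ""
    target_efficacy: float = 0.9999
    retention_confidence: float = 0.9999
    outlier_rule: str = "four_times_mean"  # or "four_over_n" / "none"
    censor: bool = False
    family: str = "auto"  # "auto" fits all four and selects by AICc
    gd_probabilities: tuple[float, ...] = (0.90, 0.95, 0.99)
    candidate_doses_gy: tuple[float, ...] = (150.0,)
    n_boot: int = 5000
    ci_level: float = 90.0
    seed: int | None = None
    bias_correct: bool = False
    compute_ci: bool = True
    slope_m: float | None = None  # %/Gy marginal-gain criterion, optional

    def __post_init__(self) -> None:
        if self.outlier_rule not in ("four_times_mean", "four_over_n", "none"):
            raise ValueError("outlier_rule must be four_times_mean, four_over_n or none")
        if self.family != "auto" and self.family not in FAMILIES:
            raise ValueError(f"family must be 'auto' or one of {FAMILIES}")
        if any(not 0 < p < 1 for p in self.gd_probabilities):
            raise ValueError("gd probabilities must lie in (0, 1)")
        if any(d <= 0 for d in self.candidate_doses_gy):
            raise ValueError("candidate doses must be > 0")
        if self.bias_correct and self.family not in ("gamma", "auto"):
            raise ValueError("bias correction applies to the gamma family only")
        if self.slope_m is not None and not self.slope_m > 0:
            raise ValueError("slope_m must be > 0")


def run_pipeline(
    config: RunConfig,
    records: Sequence[DoseRecord] | None = None,
) -> dict:
    """Execute the pipeline and return the run report dictionary.

    ``records`` may be passed directly (e.g. the packaged tables); otherwise
    they are read from ``config.input_path``.
    """
    if records is None:
        if config.input_path is None:
            raise ValueError("either records or config.input_path is required")
        records = read_dose_table(config.input_path)
    records = list(records)
    logger.info("read %d dose records", len(records))

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if config.outlier_rule != "none":
            screening = screen_outliers(records, threshold_rule=config.outlier_rule)
            kept_records = screening.kept
            removed = [
                {"species": r.species, "dose_gy": r.dose_gy, "cooks_distance": d}
                for r, d in screening.removed
            ]
            screening_info = {
                "rule": screening.threshold_rule,
                "threshold": screening.threshold,
                "model_params": screening.model_params,
                "covariates": list(screening.covariates),
                "skipped": screening.skipped,
                "removed": removed,
            }
            for r, d in screening.removed:
                logger.info(
                    "removed outlier %s at %.4g Gy (Cook's distance %.3g)",
                    r.species, r.dose_gy, d,
                )
        else:
            kept_records = records
            screening_info = {"rule": "none", "removed": []}

        policy = EfficacyPolicy(
            target_efficacy=config.target_efficacy,
            retention_confidence=config.retention_confidence,
        )
        doses = combine_all(kept_records, policy)
        logger.info("combined into %d species doses", len(doses))

        censoring_info = None
        if config.censor:
            lower_bounds = {
                r.species: r.highest_fail_dose_gy
                for r in kept_records
                if r.highest_fail_dose_gy is not None
            }
            intervals, summary = build_balanced_intervals(doses, lower_bounds)
            fit_data = intervals
            censoring_info = {
                "u_l": summary.u_l,
                "u_c": summary.u_c,
                "A": summary.A,
                "intervals": [
                    {
                        "species": iv.species,
                        "lower_gy": iv.lower_gy,
                        "reported_gy": iv.reported_gy,
                        "upper_gy": iv.upper_gy,
                        "confidence": iv.confidence,
                    }
                    for iv in intervals
                ],
            }
        else:
            fit_data = [d.dose_gy for d in doses]

        families = FAMILIES if config.family == "auto" else (config.family,)
        model_set = fit_all(fit_data, families=families)
        best = model_set.best
        logger.info("selected %s (AICc %.2f)", best.spec.family, best.aicc)

        estimates = []
        for p in config.gd_probabilities:
            if config.compute_ci:
                est = bootstrap_ci(
                    best, "gd_at_p", p,
                    n_boot=config.n_boot, level=config.ci_level, seed=config.seed,
                ).to_dict()
            else:
                from .inference import generic_dose

                est = {"statistic": "gd_at_p", "argument": p,
                       "point": generic_dose(best, p)}
            estimates.append(est)
        for dose in config.candidate_doses_gy:
            if config.compute_ci:
                est = bootstrap_ci(
                    best, "coverage_at_dose", dose,
                    n_boot=config.n_boot, level=config.ci_level, seed=config.seed,
                ).to_dict()
            else:
                from .inference import coverage_at_dose

                est = {"statistic": "coverage_at_dose", "argument": dose,
                       "point": coverage_at_dose(best, dose)}
            estimates.append(est)

        slope_info = None
        if config.slope_m is not None:
            from .inference import dose_at_marginal_gain

            criterion = dose_at_marginal_gain(best, config.slope_m)
            slope_info = {"m_pct_per_gy": criterion.m, "dose_gy": criterion.dose_gy}

        bias_info = None
        if config.bias_correct:
            gamma_fit = model_set.fits.get("gamma")
            if gamma_fit is None or not gamma_fit.converged:
                raise RuntimeError("bias correction requested but no converged gamma fit")
            corrected = coxsnell_correct_gamma(gamma_fit)
            bias_info = {
                "crude_params": dict(gamma_fit.spec.params),
                "corrected_params": corrected.corrected_params,
                "bias": corrected.bias,
                "shifts": corrected_shift(
                    corrected,
                    p_list=config.gd_probabilities,
                    dose_list=config.candidate_doses_gy,
                ),
                "corrected_coverage_pct": {
                    d: 100.0 * ssd_cdf(corrected.corrected_spec, d)
                    for d in config.candidate_doses_gy
                },
            }
        caught = sorted({str(w.message) for w in wlist})

    return {
        "config": asdict(config),
        "software": {"package": "phytossd", "version": __version__},
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "dataset": {
            "n_records": len(records),
            "n_kept_records": len(kept_records),
            "n_species": len(doses),
            "species_doses": [
                {
                    "species": d.species,
                    "dose_gy": d.dose_gy,
                    "confidence": d.confidence,
                    "n_records": d.n_records,
                }
                for d in doses
            ],
        },
        "screening": screening_info,
        "censoring": censoring_info,
        "models": model_set.table(),
        "selected_family": best.spec.family,
        "estimates": estimates,
        "slope_criterion": slope_info,
        "bias_correction": bias_info,
        "warnings": caught,
    }


def coverage_curve(
    fit_or_spec,
    dose_min: float = 1.0,
    dose_max: float | None = None,
    step: float = 1.0,
) -> list[dict]:
    """Coverage (percent) on a dose grid — the data behind an SSD curve plot."""
    spec = getattr(fit_or_spec, "spec", fit_or_spec)
    if dose_max is None:
        dose_max = float(np.ceil(spec.frozen.ppf(0.999)))
    grid = np.arange(dose_min, dose_max + step / 2, step)
    cov = 100.0 * ssd_cdf(spec, grid)
    return [{"dose_gy": float(d), "coverage_pct": float(c)} for d, c in zip(grid, cov)]
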