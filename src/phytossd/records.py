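"""Dose-table ingestion and per-species dose combination.

A literature review of phytosanitary irradiation yields one *dose record* per
study: the lowest tested dose at which no treated insect survived (here
"survival" means production of viable F1 offspring), together with the number
of specimens treated at that dose. Several studies may report doses for the
same species; those records are merged into a single per-species dose — the
unit datum of a species sensitivity distribution (SSD) fit — by a geometric
mean weighted by each record's *efficacy confidence*.

The efficacy confidence of a record is the probability that at least one of
the ``n`` treated insects would have survived if the per-insect efficacy were
exactly the target level (default 99.99%)::

    C = 1 - efficacy ** n

i.e. one minus the probability of a zero-survivor outcome under independent
per-insect survival. A record with enormous ``n`` (C ~ 1) is near-proof of the
target efficacy; a record with ``n = 12`` (C ~ 0.001) is weak evidence. When
several records for one species each carry confidence above a retention
threshold, the lowest such dose is retained outright instead of averaging.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DoseRecord",
    "SpeciesDose",
    "EfficacyPolicy",
    "confidence_of_efficacy",
    "combine_species_doses",
    "combine_all",
    "read_dose_table",
    "write_dose_table",
    "load_curculionidae",
    "load_tephritidae",
]

#: default column names of the CSV schema
DEFAULT_SCHEMA: Mapping[str, str] = {
    "species": "species",
    "family": "family",
    "dose_gy": "dose_gy",
    "n_treated": "n_treated",
    "highest_fail_dose_gy": "highest_fail_dose_gy",
    "source": "source",
}


@dataclass(frozen=True)
class DoseRecord:
    """One literature observation of a minimum effective dose.

    Parameters
    ----------
    species : str
        Binomial (optionally trinomial) name; surrounding whitespace is
        normalized.
    family : str
        Taxonomic family.
    dose_gy : float
        Reported minimum effective dose in gray (lowest tested dose with zero
        survivors).
    n_treated : int or None
        Number of specimens treated at ``dose_gy``; ``None`` when the study
        did not report it.
    highest_fail_dose_gy : float or None
        Highest tested dose at which the treatment failed (<100% efficacy);
        ``None`` when no sub-effective dose was tested or reported.
    source : str
        Citation string.
    """

    species: str
    family: str = ""
    dose_gy: float = 0.0
    n_treated: int | None = None
    highest_fail_dose_gy: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", " ".join(self.species.split()))
        if not self.species:
            raise ValueError("species name is required")
        if not self.dose_gy > 0:
            raise ValueError(f"dose_gy must be > 0, got {self.dose_gy!r}")
        if self.n_treated is not None and self.n_treated < 0:
            raise ValueError("n_treated must be >= 0")
        if self.highest_fail_dose_gy is not None:
            if not self.highest_fail_dose_gy > 0:
                raise ValueError("highest_fail_dose_gy must be > 0")
            if not self.highest_fail_dose_gy < self.dose_gy:
                raise ValueError(
                    "highest_fail_dose_gy must lie below the effective dose"
                )


@dataclass(frozen=True)
class SpeciesDose:
    """A single combined per-species dose entering the SSD fit."""

    species: str
    dose_gy: float
    confidence: float | None = None  # efficacy confidence C, None if no n known
    n_records: int = 1
    n_treated: int | None = None  # total specimens behind the combined dose

    def __post_init__(self) -> None:
        if not self.dose_gy > 0:
            raise ValueError("dose_gy must be > 0")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


@dataclass(frozen=True)
class EfficacyPolicy:
    """Targets governing confidence weighting and dose retention.

    ``target_efficacy`` is the per-insect kill proportion the reported doses
    are meant to prove (0.9999, the probit-8.72 convention). Records whose
    confidence exceeds ``retention_confidence`` are treated as conclusive: the
    lowest such dose is retained instead of a weighted average.
    """

    target_efficacy: float = 0.9999
    retention_confidence: float = 0.9999

    def __post_init__(self) -> None:
        for name in ("target_efficacy", "retention_confidence"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")


def confidence_of_efficacy(n: int, target_efficacy: float = 0.9999) -> float:
    """Confidence that ``n`` zero-survivor insects prove the target efficacy.

    Returns ``C = 1 - target_efficacy ** n``: the probability of observing at
    least one survivor among ``n`` independently treated insects whose
    individual kill probability equals ``target_efficacy``. It is 0 at
    ``n = 0`` and non-decreasing in ``n``. The classical probit-9 benchmark
    (efficacy 0.999968, n = 93,613) evaluates to ~0.95.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 < target_efficacy < 1.0:
        raise ValueError("target_efficacy must lie strictly in (0, 1)")
    # evaluate via expm1/log for very large n
    return -math.expm1(n * math.log(target_efficacy))


def combine_species_doses(
    records: Sequence[DoseRecord],
    policy: EfficacyPolicy | None = None,
) -> SpeciesDose:
    """Merge all records for one species into a single SSD input dose.

    If any record's confidence exceeds ``policy.retention_confidence``, the
    lowest dose among those conclusive records is retained. Otherwise the
    combined dose is the geometric mean of the reported doses weighted by
    their confidences, ``exp(sum(C_i * ln D_i) / sum(C_i))``, which always
    lies between the minimum and maximum reported dose. Records with unknown
    ``n`` carry no weight; if no record has a usable weight the unweighted
    geometric mean is used with a warning.
    """
    if not records:
        raise ValueError("records must be non-empty")
    policy = policy or EfficacyPolicy()
    species = records[0].species
    if any(r.species != species for r in records):
        raise ValueError("all records must belong to the same species")

    ns = [r.n_treated for r in records]
    total_n = sum(n for n in ns if n) or None
    confs = [
        confidence_of_efficacy(n, policy.target_efficacy) if n is not None else None
        for n in ns
    ]
    combined_conf = (
        confidence_of_efficacy(total_n, policy.target_efficacy) if total_n else None
    )

    if len(records) == 1:
        return SpeciesDose(
            species=species,
            dose_gy=records[0].dose_gy,
            confidence=confs[0],
            n_records=1,
            n_treated=ns[0],
        )

    conclusive = [
        r
        for r, c in zip(records, confs)
        if c is not None and c > policy.retention_confidence
    ]
    if conclusive:
        dose = min(r.dose_gy for r in conclusive)
        logger.info(
            "%s: retained lowest conclusive dose %.4g Gy of %d records",
            species, dose, len(records),
        )
        return SpeciesDose(
            species=species,
            dose_gy=dose,
            confidence=combined_conf,
            n_records=len(records),
            n_treated=total_n,
        )

    weights = [c if c is not None else 0.0 for c in confs]
    wsum = sum(weights)
    if wsum <= 0.0:
        warnings.warn(
            f"{species}: no record has a usable specimen count; "
            "falling back to the unweighted geometric mean",
            stacklevel=2,
        )
        weights = [1.0] * len(records)
        wsum = float(len(records))
    log_dose = sum(w * math.log(r.dose_gy) for w, r in zip(weights, records)) / wsum
    return SpeciesDose(
        species=species,
        dose_gy=math.exp(log_dose),
        confidence=combined_conf,
        n_records=len(records),
        n_treated=total_n,
    )


def combine_all(
    records: Iterable[DoseRecord],
    policy: EfficacyPolicy | None = None,
) -> list[SpeciesDose]:
    """Group records by species (input order of first appearance) and combine."""
    groups: dict[str, list[DoseRecord]] = {}
    for r in records:
        groups.setdefault(r.species, []).append(r)
    return [combine_species_doses(g, policy) for g in groups.values()]


def _parse_cell(value, row: int, column: str, kind: str):
    """Parse one CSV cell; '', '-', NaN are missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text in ("", "-", "–", "—", "NA", "NaN"):
        return None
    try:
        if kind == "int":
            number = float(text.replace(",", ""))
            if not number.is_integer():
                raise ValueError
            return int(number)
        return float(text)
    except ValueError:
        raise ValueError(
            f"row {row}: column {column!r} has non-numeric value {text!r}"
        ) from None


def read_dose_table(
    path,
    schema: Mapping[str, str] | None = None,
) -> list[DoseRecord]:
    """Read a dose table CSV into a list of :class:`DoseRecord`.

    ``schema`` maps canonical field names (``species``, ``family``,
    ``dose_gy``, ``n_treated``, ``highest_fail_dose_gy``, ``source``) to the
    column names used in the file. Missing ``n_treated`` or
    ``highest_fail_dose_gy`` cells (empty or "-") become ``None``. Validation
    errors name the offending row and column.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty or has no header") from None
    missing = [schema[k] for k in ("species", "dose_gy") if schema[k] not in frame.columns]
    if missing:
        raise ValueError(f"{path}: required column(s) missing: {missing}")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")

    records: list[DoseRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        dose = _parse_cell(row[schema["dose_gy"]], i, schema["dose_gy"], "float")
        if dose is None or dose <= 0:
            raise ValueError(
                f"row {i}: column {schema['dose_gy']!r} must be a positive dose, "
                f"got {row[schema['dose_gy']]!r}"
            )
        n = (
            _parse_cell(row[schema["n_treated"]], i, schema["n_treated"], "int")
            if schema["n_treated"] in frame.columns
            else None
        )
        fail = (
            _parse_cell(
                row[schema["highest_fail_dose_gy"]], i,
                schema["highest_fail_dose_gy"], "float",
            )
            if schema["highest_fail_dose_gy"] in frame.columns
            else None
        )
        try:
            records.append(
                DoseRecord(
                    species=row[schema["species"]],
                    family=str(row.get(schema["family"], "") or ""),
                    dose_gy=dose,
                    n_treated=n,
                    highest_fail_dose_gy=fail,
                    source=str(row.get(schema["source"], "") or ""),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
    return records


def write_dose_table(records: Sequence[DoseRecord], path) -> None:
    """Write records to CSV in the canonical schema (round-trips losslessly)."""
    frame = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "family": [r.family for r in records],
            "dose_gy": [r.dose_gy for r in records],
            "n_treated": pd.array(
                [r.n_treated for r in records], dtype="Int64"
            ),
            "highest_fail_dose_gy": [r.highest_fail_dose_gy for r in records],
            "source": [r.source for r in records],
        }
    )
    frame.to_csv(path, index=False)


def _load_packaged(name: str) -> list[DoseRecord]:
    ref = resources.files("phytossd.data").joinpath(name)
    with resources.as_file(ref) as p:
        return read_dose_table(p)


def load_curculionidae() -> list[DoseRecord]:
    """The packaged Curculionidae literature table (31 records, 28 species)."""
    return _load_packaged("curculionidae_table1.csv")


def load_tephritidae() -> list[DoseRecord]:
    """The packaged Tephritidae combined-dose table (15 species)."""
    return _load_packaged("tephritidae_table3.csv")
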