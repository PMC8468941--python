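"""Classify study-group means against normative bands.

Each study-group mean is placed in one of six ordered categories relative to
the fitted curve's confidence and prediction bounds at the group's mean age,
and additionally standardized into a continuous z-score. Inner interval
boundaries are closed (a value exactly on ``ci_lo`` counts as inside the CI);
a value exactly equal to the fitted mean is assigned ``within_CI_below``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateBandError, DomainError, ExtrapolationError, StateError
from .normative_model import MEASURES, GrowthFit, IntervalBand
from .study_table import StudyGroupRecord, compute_relative_volume

#: Ordinal categories, lowest (furthest below the curve) first.
CATEGORIES = (
    "below_PI",
    "below_CI",
    "within_CI_below",
    "within_CI_above",
    "above_CI",
    "above_PI",
)

CATEGORY_RANK = {name: rank for rank, name in enumerate(CATEGORIES)}

BandValues = Tuple[float, float, float, float, float]  # mean, ci_lo, ci_hi, pi_lo, pi_hi


@dataclass(frozen=True)
class DeviationCall:
    """One study group × one measure: ordinal band category plus z-score."""

    study_id: str
    group_label: str
    measure: str
    age_years: float
    n: int
    observed_mean: float
    fitted_mean: float
    ci_lo: float
    ci_hi: float
    pi_lo: float
    pi_hi: float
    category: str
    z_score: float


def band_at_age(band: IntervalBand, age: float) -> BandValues:
    """Linearly interpolate the band at ``age``; never extrapolates."""
    ages = band.ages
    if not ages[0] <= age <= ages[-1]:
        raise ExtrapolationError(
            f"age {age} outside band grid [{ages[0]}, {ages[-1]}]"
        )
    return (
        float(np.interp(age, ages, band.mean)),
        float(np.interp(age, ages, band.ci_lo)),
        float(np.interp(age, ages, band.ci_hi)),
        float(np.interp(age, ages, band.pi_lo)),
        float(np.interp(age, ages, band.pi_hi)),
    )


def _check_band_values(band_values: BandValues) -> None:
    mean, ci_lo, ci_hi, pi_lo, pi_hi = band_values
    if not pi_lo <= ci_lo <= mean <= ci_hi <= pi_hi:
        raise StateError(f"malformed band values: {band_values}")


def classify_deviation(observed_mean: float, band_values: BandValues) -> str:
    """Place an observed mean into one of the six ordered band categories."""
    _check_band_values(band_values)
    mean, ci_lo, ci_hi, pi_lo, pi_hi = band_values
    if observed_mean < pi_lo:
        return "below_PI"
    if observed_mean < ci_lo:
        return "below_CI"
    if observed_mean <= mean:
        return "within_CI_below"
    if observed_mean <= ci_hi:
        return "within_CI_above"
    if observed_mean <= pi_hi:
        return "above_CI"
    return "above_PI"


def standardized_deviation(
    observed_mean: float,
    fitted_mean: float,
    band_values: BandValues,
    fit_sigma: float,
    level: float = 0.95,
    df: Optional[int] = None,
) -> float:
    """Continuous companion to the ordinal category.

    ``z = (observed - fitted) / sqrt(s_mean**2 + sigma**2)`` where ``s_mean``
    is recovered from the CI half-width and the t-quantile (normal quantile
    when ``df`` is None).
    """
    _check_band_values(band_values)
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0, 1), got {level}")
    _, ci_lo, ci_hi, _, _ = band_values
    quantile = (
        stats.norm.ppf(1 - (1 - level) / 2)
        if df is None
        else stats.t.ppf(1 - (1 - level) / 2, df)
    )
    s_mean = (ci_hi - ci_lo) / (2.0 * quantile)
    variance = s_mean**2 + fit_sigma**2
    if not variance > 0:
        raise DegenerateBandError("zero predictive variance; z-score undefined")
    return (observed_mean - fitted_mean) / float(np.sqrt(variance))


def _observed_for_measure(record: StudyGroupRecord, measure: str) -> float:
    if measure == "GMV":
        value = record.gmv_mean_cm3
    elif measure == "WMV":
        value = record.wmv_mean_cm3
    elif measure == "TIV":
        value = record.tiv_mean_cm3
    elif measure == "GMV_over_TIV":
        value = compute_relative_volume(record.gmv_mean_cm3, record.tiv_mean_cm3)
    elif measure == "WMV_over_TIV":
        value = compute_relative_volume(record.wmv_mean_cm3, record.tiv_mean_cm3)
    else:
        raise DomainError(f"unknown measure {measure!r}")
    if value is None:
        raise DomainError(f"record {record.label} lacks a value for {measure}")
    return float(value)


def contrast_table(
    records: Sequence[StudyGroupRecord],
    fits: Mapping[str, tuple[GrowthFit, IntervalBand]],
) -> list[DeviationCall]:
    """One :class:`DeviationCall` per record × measure, ordered by measure then age."""
    calls: list[DeviationCall] = []
    measure_order = [m for m in MEASURES if m in fits] + [
        m for m in fits if m not in MEASURES
    ]
    for measure in measure_order:
        fit, band = fits[measure]
        for record in sorted(records, key=lambda r: (r.age_years, r.study_id, r.group_label)):
            try:
                band_values = band_at_age(band, record.age_years)
            except ExtrapolationError as exc:
                raise ExtrapolationError(f"record {record.label}: {exc}") from exc
            observed = _observed_for_measure(record, measure)
            mean, ci_lo, ci_hi, pi_lo, pi_hi = band_values
            calls.append(
                DeviationCall(
                    study_id=record.study_id,
                    group_label=record.group_label,
                    measure=measure,
                    age_years=record.age_years,
                    n=record.n,
                    observed_mean=observed,
                    fitted_mean=mean,
                    ci_lo=ci_lo,
                    ci_hi=ci_hi,
                    pi_lo=pi_lo,
                    pi_hi=pi_hi,
                    category=classify_deviation(observed, band_values),
                    z_score=standardized_deviation(
                        observed, mean, band_values, fit.sigma, band.level, fit.df
                    ),
                )
            )
    return calls


def category_counts(calls: Sequence[DeviationCall]) -> dict[str, dict[str, int]]:
    """Calls per category per measure (all six categories always present)."""
    counts: dict[str, dict[str, int]] = {}
    for call in calls:
        per_measure = counts.setdefault(call.measure, {c: 0 for c in CATEGORIES})
        per_measure[call.category] += 1
    return counts


def calls_to_frame(calls: Sequence[DeviationCall]):
    """Contrast table as a pandas DataFrame in the output column order."""
    import pandas as pd

    columns = [f.name for f in dataclasses.fields(DeviationCall)]
    return pd.DataFrame([dataclasses.asdict(c) for c in calls], columns=columns)
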