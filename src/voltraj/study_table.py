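"""Parse, validate, normalize, filter and summarize study-level volumetric tables.

A *study group* is one published (sub)group of preterm-born subjects with a
mean age at scan and mean/SD brain volumes. The module reads and writes a flat
CSV schema (comma-separated, UTF-8, ``.`` decimal separator, empty string =
missing), harmonizes units, applies the eligibility and cohort-deduplication
rules, and produces simple cohort accounting summaries.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import (
    DomainError,
    EmptyInputError,
    RowParseError,
    SchemaError,
    UnitError,
)

logger = logging.getLogger(__name__)

#: Columns that must be present in any study-table CSV.
REQUIRED_COLUMNS = ("study_id", "n", "age_years")

#: Volume columns; at least one mean must be present in the header.
VOLUME_MEAN_COLUMNS = ("tiv_mean_cm3", "gmv_mean_cm3", "wmv_mean_cm3")

#: Full column order used when writing records back to CSV.
CSV_COLUMNS = (
    "study_id",
    "group_label",
    "cohort_id",
    "n",
    "age_years",
    "tiv_mean_cm3",
    "tiv_sd_cm3",
    "gmv_mean_cm3",
    "gmv_sd_cm3",
    "wmv_mean_cm3",
    "wmv_sd_cm3",
    "ga_weeks",
    "bw_grams",
    "male_pct",
    "country",
    "segmentation_method",
)

_PACKAGED_TABLE = "preterm_studies.csv"


@dataclass(frozen=True)
class StudyGroupRecord:
    """One row of a study-summary table: a (sub)group of preterm subjects."""

    study_id: str
    group_label: str = ""
    cohort_id: str = ""
    n: int = 0
    age_years: float = 0.0
    tiv_mean_cm3: Optional[float] = None
    tiv_sd_cm3: Optional[float] = None
    gmv_mean_cm3: Optional[float] = None
    gmv_sd_cm3: Optional[float] = None
    wmv_mean_cm3: Optional[float] = None
    wmv_sd_cm3: Optional[float] = None
    ga_weeks: Optional[float] = None
    bw_grams: Optional[float] = None
    male_pct: Optional[float] = None
    country: str = ""
    segmentation_method: str = ""

    def validate(self) -> None:
        """Raise :class:`DomainError` on any invariant violation."""
        if not self.study_id:
            raise DomainError("study_id must be non-empty")
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if not self.age_years > 0:
            raise DomainError(f"age_years must be > 0, got {self.age_years}")
        for name in (
            "tiv_mean_cm3",
            "tiv_sd_cm3",
            "gmv_mean_cm3",
            "gmv_sd_cm3",
            "wmv_mean_cm3",
            "wmv_sd_cm3",
        ):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise DomainError(f"{name} must be > 0 when present, got {value}")
        if (
            self.tiv_mean_cm3 is not None
            and self.gmv_mean_cm3 is not None
            and self.wmv_mean_cm3 is not None
            and not self.gmv_mean_cm3 + self.wmv_mean_cm3 < self.tiv_mean_cm3
        ):
            raise DomainError(
                "gmv_mean_cm3 + wmv_mean_cm3 must be < tiv_mean_cm3 "
                f"({self.gmv_mean_cm3} + {self.wmv_mean_cm3} vs {self.tiv_mean_cm3})"
            )
        if self.male_pct is not None and not 0 <= self.male_pct <= 100:
            raise DomainError(f"male_pct must be in [0, 100], got {self.male_pct}")

    @property
    def label(self) -> str:
        """Human-readable row identifier (study id plus optional group)."""
        return f"{self.study_id}/{self.group_label}" if self.group_label else self.study_id


@dataclass(frozen=True)
class CohortSummary:
    """Accounting over a set of study-group records."""

    total_n: int
    n_groups: int
    n_studies: int
    age_min_years: float
    age_max_years: float


def _parse_float(cell: str, column: str, row_index: int) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise RowParseError(row_index, f"non-numeric {column}: {cell!r}") from exc


def _parse_int(cell: str, column: str, row_index: int) -> int:
    cell = cell.strip()
    try:
        value = float(cell)
    except ValueError as exc:
        raise RowParseError(row_index, f"non-numeric {column}: {cell!r}") from exc
    if value != int(value):
        raise RowParseError(row_index, f"{column} must be an integer, got {cell!r}")
    return int(value)


def parse_study_table(path: str | Path) -> list[StudyGroupRecord]:
    """Read a study-table CSV into validated :class:`StudyGroupRecord` rows.

    Raises
    ------
    SchemaError
        If a required column is absent or no volume column is present.
    EmptyInputError
        If the file is empty (no header at all).
    RowParseError
        On a malformed data row; carries the zero-based data-row index.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path} is empty")
        fields = [f.strip() for f in reader.fieldnames]
        for column in REQUIRED_COLUMNS:
            if column not in fields:
                raise SchemaError(f"missing required column {column!r} in {path}")
        if not any(column in fields for column in VOLUME_MEAN_COLUMNS):
            raise SchemaError(
                f"at least one of {VOLUME_MEAN_COLUMNS} is required in {path}"
            )
        records: list[StudyGroupRecord] = []
        for row_index, row in enumerate(reader):
            get = lambda col: (row.get(col) or "").strip()  # noqa: E731
            record = StudyGroupRecord(
                study_id=get("study_id"),
                group_label=get("group_label"),
                cohort_id=get("cohort_id"),
                n=_parse_int(get("n"), "n", row_index),
                age_years=_parse_float(get("age_years"), "age_years", row_index) or 0.0,
                tiv_mean_cm3=_parse_float(get("tiv_mean_cm3"), "tiv_mean_cm3", row_index),
                tiv_sd_cm3=_parse_float(get("tiv_sd_cm3"), "tiv_sd_cm3", row_index),
                gmv_mean_cm3=_parse_float(get("gmv_mean_cm3"), "gmv_mean_cm3", row_index),
                gmv_sd_cm3=_parse_float(get("gmv_sd_cm3"), "gmv_sd_cm3", row_index),
                wmv_mean_cm3=_parse_float(get("wmv_mean_cm3"), "wmv_mean_cm3", row_index),
                wmv_sd_cm3=_parse_float(get("wmv_sd_cm3"), "wmv_sd_cm3", row_index),
                ga_weeks=_parse_float(get("ga_weeks"), "ga_weeks", row_index),
                bw_grams=_parse_float(get("bw_grams"), "bw_grams", row_index),
                male_pct=_parse_float(get("male_pct"), "male_pct", row_index),
                country=get("country"),
                segmentation_method=get("segmentation_method"),
            )
            try:
                record.validate()
            except DomainError as exc:
                raise RowParseError(row_index, str(exc)) from exc
            records.append(record)
    return records


def load_packaged_study_table() -> list[StudyGroupRecord]:
    """Load the CSV fixture shipped with the package (14 group rows)."""
    with resources.as_file(
        resources.files("voltraj").joinpath("data", _PACKAGED_TABLE)
    ) as path:
        return parse_study_table(path)


def write_study_table(records: Iterable[StudyGroupRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column order (missing → empty)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for record in records:
            row = []
            for column in CSV_COLUMNS:
                value = getattr(record, column)
                row.append("" if value is None else value)
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Unit harmonization
# ---------------------------------------------------------------------------

def convert_age(value: float, unit: str) -> float:
    """Convert an age to years. ``unit`` is one of ``{"years", "months"}``."""
    if not value > 0:
        raise DomainError(f"age must be > 0, got {value}")
    if unit == "years":
        return float(value)
    if unit == "months":
        return value / 12.0
    raise UnitError(f"unknown age unit {unit!r}")


def convert_volume(value: float, unit: str) -> float:
    """Convert a volume to cm³. ``unit`` is one of ``{"cm3", "mm3", "dm3"}``."""
    if not value > 0:
        raise DomainError(f"volume must be > 0, got {value}")
    if unit == "cm3":
        return float(value)
    if unit == "mm3":
        return value / 1000.0
    if unit == "dm3":
        return value * 1000.0
    raise UnitError(f"unknown volume unit {unit!r}")


def convert_weight(value: float, unit: str) -> float:
    """Convert a weight to grams. ``unit`` is one of ``{"g", "kg"}``."""
    if not value > 0:
        raise DomainError(f"weight must be > 0, got {value}")
    if unit == "g":
        return float(value)
    if unit == "kg":
        return value * 1000.0
    raise UnitError(f"unknown weight unit {unit!r}")


def derive_volume_from_ratio(ratio: float, tiv_cm3: float) -> float:
    """Recover an absolute volume (cm³) from a tissue/TIV ratio."""
    if not 0 < ratio < 1:
        raise DomainError(f"ratio must be in (0, 1), got {ratio}")
    if not tiv_cm3 > 0:
        raise DomainError(f"tiv_cm3 must be > 0, got {tiv_cm3}")
    return ratio * tiv_cm3


def compute_relative_volume(vol_cm3: float, tiv_cm3: float) -> float:
    """Tissue volume divided by TIV (unitless fraction)."""
    if not vol_cm3 > 0:
        raise DomainError(f"vol_cm3 must be > 0, got {vol_cm3}")
    if not tiv_cm3 > 0:
        raise DomainError(f"tiv_cm3 must be > 0, got {tiv_cm3}")
    return vol_cm3 / tiv_cm3


# ---------------------------------------------------------------------------
# Eligibility and deduplication
# ---------------------------------------------------------------------------

#: Exclusion reason labels used by the eligibility report.
REASON_AGE = "age <= {min_age}"
REASON_MISSING = "missing measure"


def eligibility_exclusions(
    records: Sequence[StudyGroupRecord], min_age_years: float = 1.0
) -> list[tuple[StudyGroupRecord, str]]:
    """List excluded records with reasons; complements :func:`filter_eligible`."""
    excluded: list[tuple[StudyGroupRecord, str]] = []
    for record in records:
        if not record.age_years > min_age_years:
            excluded.append((record, REASON_AGE.format(min_age=min_age_years)))
        elif any(
            getattr(record, column) is None for column in VOLUME_MEAN_COLUMNS
        ):
            excluded.append((record, REASON_MISSING))
    return excluded


def filter_eligible(
    records: Sequence[StudyGroupRecord], min_age_years: float = 1.0
) -> list[StudyGroupRecord]:
    """Keep records with mean age strictly above ``min_age_years`` and all of
    TIV, GMV and WMV present. Order is preserved; exclusions are logged."""
    excluded = {id(r) for r, _ in eligibility_exclusions(records, min_age_years)}
    for record, reason in eligibility_exclusions(records, min_age_years):
        logger.info("excluded %s: %s", record.label, reason)
    return [r for r in records if id(r) not in excluded]


def write_exclusion_report(
    records: Sequence[StudyGroupRecord],
    path: str | Path,
    min_age_years: float = 1.0,
) -> None:
    """Write the eligibility exclusion report as CSV (record label, reason)."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["record", "reason"])
        for record, reason in eligibility_exclusions(records, min_age_years):
            writer.writerow([record.label, reason])


def select_largest_per_cohort(
    records: Sequence[StudyGroupRecord], age_tolerance_years: float = 0.0
) -> list[StudyGroupRecord]:
    """Deduplicate same-cohort records reported at (about) the same age.

    Records sharing ``cohort_id`` whose ages fall in the same tolerance-linked
    cluster compete; only records from the study with the largest total ``n``
    in that cluster are retained. Same-cohort records at distinct ages are all
    kept. Ties on total ``n`` resolve to the lexicographically smallest
    ``study_id`` with a logged warning.
    """
    if age_tolerance_years < 0:
        raise DomainError("age_tolerance_years must be >= 0")
    keep: set[int] = set()
    by_cohort: dict[str, list[StudyGroupRecord]] = {}
    for record in records:
        by_cohort.setdefault(record.cohort_id, []).append(record)
    for cohort_records in by_cohort.values():
        ordered = sorted(cohort_records, key=lambda r: r.age_years)
        # chain adjacent ages: gap <= tolerance links records into one cluster,
        # which equals connected components of the pairwise |Δage|<=tol graph
        clusters: list[list[StudyGroupRecord]] = []
        for record in ordered:
            if (
                clusters
                and record.age_years - clusters[-1][-1].age_years
                <= age_tolerance_years
            ):
                clusters[-1].append(record)
            else:
                clusters.append([record])
        for cluster in clusters:
            totals: dict[str, int] = {}
            for record in cluster:
                totals[record.study_id] = totals.get(record.study_id, 0) + record.n
            best_n = max(totals.values())
            winners = sorted(s for s, total in totals.items() if total == best_n)
            if len(winners) > 1:
                logger.warning(
                    "tie on total n=%d among studies %s; keeping %s",
                    best_n,
                    winners,
                    winners[0],
                )
            winner = winners[0]
            keep.update(id(r) for r in cluster if r.study_id == winner)
    return [r for r in records if id(r) in keep]


def summarize_cohort(records: Sequence[StudyGroupRecord]) -> CohortSummary:
    """Total subjects, group/study counts and the mean-age range."""
    if not records:
        raise EmptyInputError("cannot summarize an empty record list")
    ages = [r.age_years for r in records]
    return CohortSummary(
        total_n=sum(r.n for r in records),
        n_groups=len(records),
        n_studies=len({r.study_id for r in records}),
        age_min_years=min(ages),
        age_max_years=max(ages),
    )


def records_to_frame(records: Sequence[StudyGroupRecord]):
    """Records as a pandas DataFrame in canonical column order."""
    import pandas as pd

    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records], columns=list(CSV_COLUMNS)
    )
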