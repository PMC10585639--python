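"""ETDRS-grid thickness data model and deterministic CSV round-trip.

The unit of observation is one eye of one subject: a 9-sector ETDRS
macular thickness map (central fovea, 4 parafoveal and 4 perifoveal
quadrants, all in micrometres) plus an optional central choroidal
thickness, together with subject covariates (ethnicity, age, sex) and
laterality. A :class:`Cohort` is an ordered collection of such records
with cluster invariants enforced: at most two eyes per subject and
constant covariates within a subject.

Files are plain comma-separated UTF-8 with a fixed column order and
two-decimal thickness formatting, so that write → read → write is
byte-identical.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SECTORS",
    "RESPONSES",
    "ETHNICITIES",
    "EtdrsGrid",
    "EyeRecord",
    "Cohort",
    "CohortIntegrityError",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "orient_grid",
]

#: ETDRS sector column names: central fovea, parafoveal ring (p_*,
#: 1-3 mm), perifoveal ring (f_*, 3-6 mm); each ring split into
#: superior / nasal / inferior / temporal quadrants.
SECTORS: tuple[str, ...] = (
    "c0",
    "p_sup", "p_nas", "p_inf", "p_tem",
    "f_sup", "f_nas", "f_inf", "f_tem",
)

#: Analyzable responses: the nine retinal sectors plus the central choroid.
RESPONSES: tuple[str, ...] = SECTORS + ("choroid",)

ETHNICITIES = ("Ghanaian", "European")
SEXES = ("female", "male")
EYES = ("OD", "OS")

CSV_COLUMNS = ("subject_id", "ethnicity", "age", "sex", "eye", *SECTORS, "choroid")

_FIELD_BY_SECTOR = {
    "c0": "center_fovea",
    "p_sup": "parafovea_superior",
    "p_nas": "parafovea_nasal",
    "p_inf": "parafovea_inferior",
    "p_tem": "parafovea_temporal",
    "f_sup": "perifovea_superior",
    "f_nas": "perifovea_nasal",
    "f_inf": "perifovea_inferior",
    "f_tem": "perifovea_temporal",
}


class CohortIntegrityError(ValueError):
    """A cohort invariant is violated (duplicate eye, covariate conflict...)."""


class CohortParseError(ValueError):
    """A CSV row could not be parsed; the message names the offending row."""


@dataclass(frozen=True)
class EtdrsGrid:
    """Thickness (μm) in the nine ETDRS sectors of one macula."""

    center_fovea: float
    parafovea_superior: float
    parafovea_nasal: float
    parafovea_inferior: float
    parafovea_temporal: float
    perifovea_superior: float
    perifovea_nasal: float
    perifovea_inferior: float
    perifovea_temporal: float

    def __post_init__(self) -> None:
        for sector in SECTORS:
            value = self[sector]
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"sector {sector!r} must be finite and > 0, got {value!r}"
                )

    def __getitem__(self, sector: str) -> float:
        try:
            return getattr(self, _FIELD_BY_SECTOR[sector])
        except KeyError:
            raise KeyError(f"unknown ETDRS sector {sector!r}") from None

    def as_dict(self) -> dict[str, float]:
        """Sector-name → thickness mapping in canonical column order."""
        return {s: self[s] for s in SECTORS}


@dataclass(frozen=True)
class EyeRecord:
    """One eye's measurements with its subject's covariates."""

    subject_id: str
    ethnicity: str
    age: float
    sex: str
    eye: str
    grid: EtdrsGrid
    choroid: float | None = None

    def __post_init__(self) -> None:
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"ethnicity must be one of {ETHNICITIES}, got {self.ethnicity!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if not (18.0 <= self.age <= 110.0):
            raise ValueError(f"age must lie in [18, 110] years, got {self.age!r}")
        if self.choroid is not None and not (math.isfinite(self.choroid) and self.choroid > 0):
            raise ValueError(f"choroid must be finite and > 0 when present, got {self.choroid!r}")

    def response(self, name: str) -> float | None:
        """Value of a retinal sector or the choroid for this eye."""
        if name == "choroid":
            return self.choroid
        return self.grid[name]


@dataclass
class Cohort:
    """Ordered per-eye records with subject-level integrity guarantees."""

    records: list[EyeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], int] = {}
        covariates: dict[str, tuple[str, float, str]] = {}
        for i, rec in enumerate(self.records):
            key = (rec.subject_id, rec.eye)
            if key in seen:
                raise CohortIntegrityError(
                    f"duplicate eye {rec.eye} for subject {rec.subject_id!r} "
                    f"(records {seen[key]} and {i})"
                )
            seen[key] = i
            cov = (rec.ethnicity, rec.age, rec.sex)
            if covariates.setdefault(rec.subject_id, cov) != cov:
                raise CohortIntegrityError(
                    f"conflicting covariates for subject {rec.subject_id!r}: "
                    f"{covariates[rec.subject_id]} vs {cov}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_subjects(self) -> int:
        return len({r.subject_id for r in self.records})

    def subjects(self) -> dict[str, list[EyeRecord]]:
        """Records grouped by subject, insertion order preserved."""
        out: dict[str, list[EyeRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.subject_id, []).append(rec)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long per-eye table with one column per response (choroid may be NaN)."""
        rows = []
        for rec in self.records:
            row = {
                "subject_id": rec.subject_id,
                "ethnicity": rec.ethnicity,
                "age": rec.age,
                "sex": rec.sex,
                "eye": rec.eye,
                **rec.grid.as_dict(),
                "choroid": float("nan") if rec.choroid is None else rec.choroid,
            }
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def orient_grid(grid: EtdrsGrid, eye: str) -> EtdrsGrid:
    """Resolve a screen-coordinate thickness map to anatomical orientation.

    Right-eye (OD) maps are the canonical template, so OD is the
    identity. For a left eye exported in screen coordinates the
    horizontal axis is mirrored, which exchanges the nasal and temporal
    quadrants of both rings; superior/inferior are unaffected. Applying
    the OS transform twice returns the original grid.

    Device software that already labels quadrants anatomically needs no
    orientation step; :func:`read_cohort` therefore only calls this when
    asked (``screen_coordinates=True``).
    """
    if eye not in EYES:
        raise ValueError(f"eye must be one of {EYES}, got {eye!r}")
    if eye == "OD":
        return grid
    return replace(
        grid,
        parafovea_nasal=grid.parafovea_temporal,
        parafovea_temporal=grid.parafovea_nasal,
        perifovea_nasal=grid.perifovea_temporal,
        perifovea_temporal=grid.perifovea_nasal,
    )


def _parse_float(text: str, column: str, row_number: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise CohortParseError(
            f"row {row_number}: column {column!r} is not a number: {text!r}"
        ) from None


def read_cohort(path: str | Path, *, screen_coordinates: bool = False) -> Cohort:
    """Read a per-eye thickness CSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file with header ``subject_id,ethnicity,age,sex,eye,c0,...,choroid``.
        A missing choroid is an empty field; retinal sectors must be complete.
    screen_coordinates
        If true, OS grids are mirrored to anatomical orientation via
        :func:`orient_grid`.

    Raises
    ------
    CohortParseError
        Malformed row (names the 1-based data row number).
    CohortIntegrityError
        Duplicate (subject, eye) or covariate conflict within a subject.
    """
    path = Path(path)
    records: list[EyeRecord] = []
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(f"{path}: empty file, expected header") from None
        if tuple(header) != CSV_COLUMNS:
            raise CohortParseError(
                f"{path}: bad header {header!r}; expected {list(CSV_COLUMNS)}"
            )
        for row_number, row in enumerate(reader, start=1):
            if len(row) != len(CSV_COLUMNS):
                raise CohortParseError(
                    f"row {row_number}: expected {len(CSV_COLUMNS)} fields, got {len(row)}"
                )
            data = dict(zip(CSV_COLUMNS, row))
            for column in SECTORS:
                if data[column] == "":
                    raise CohortParseError(
                        f"row {row_number}: retinal sector {column!r} is empty; "
                        "rows must carry a complete 9-sector map"
                    )
            try:
                grid = EtdrsGrid(
                    **{
                        _FIELD_BY_SECTOR[s]: _parse_float(data[s], s, row_number)
                        for s in SECTORS
                    }
                )
                if screen_coordinates:
                    grid = orient_grid(grid, data["eye"])
                record = EyeRecord(
                    subject_id=data["subject_id"],
                    ethnicity=data["ethnicity"],
                    age=_parse_float(data["age"], "age", row_number),
                    sex=data["sex"],
                    eye=data["eye"],
                    grid=grid,
                    choroid=None
                    if data["choroid"] == ""
                    else _parse_float(data["choroid"], "choroid", row_number),
                )
            except CohortParseError:
                raise
            except ValueError as exc:
                raise CohortParseError(f"row {row_number}: {exc}") from None
            records.append(record)
    return Cohort(records=records, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in canonical form: fixed column order, 2-decimal
    thicknesses, empty field for a missing choroid, LF line endings."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for rec in cohort.records:
            row: list[str] = [rec.subject_id, rec.ethnicity, f"{rec.age:.2f}", rec.sex, rec.eye]
            row.extend(f"{rec.grid[s]:.2f}" for s in SECTORS)
            row.append("" if rec.choroid is None else f"{rec.choroid:.2f}")
            writer.writerow(row)


def cohort_from_rows(rows: Iterable[dict], provenance: str = "") -> Cohort:
    """Build a cohort from dicts keyed like the CSV columns (testing aid)."""
    records = []
    for row in rows:
        grid = EtdrsGrid(**{_FIELD_BY_SECTOR[s]: row[s] for s in SECTORS})
        records.append(
            EyeRecord(
                subject_id=row["subject_id"],
                ethnicity=row["ethnicity"],
                age=row["age"],
                sex=row["sex"],
                eye=row["eye"],
                grid=grid,
                choroid=row.get("choroid"),
            )
        )
    return Cohort(records=records, provenance=provenance)
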