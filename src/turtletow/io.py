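"""Domain types and CSV I/O for towed-diver sea turtle survey data.

The analysis atom is a single 5-minute tow segment (~220 m of a ~2.2 km,
50-minute tow): the number of turtles a diver pair recorded on that segment,
the species, and the estimated average total length. Segments with zero
turtles are explicit rows — the count models are zero-inflation-aware and
must see the zeros.

CSV dialect: comma-separated, UTF-8, header row required, '.' decimal mark.
Column names are frozen in the README. A count-0 row carries the placeholder
species "green"; species on a zero row carries no information and every
consumer ignores it (see `segment_count_series`).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Region",
    "Species",
    "SegmentObservation",
    "SiteMetadata",
    "DriverRecord",
    "ValidationReport",
    "SchemaError",
    "ValidationError",
    "read_segments",
    "write_segments",
    "read_sites",
    "write_sites",
    "read_drivers",
    "write_drivers",
    "segments_to_frame",
    "frame_to_segments",
    "validate_dataset",
    "segment_count_series",
    "nominal_segment_length_m",
]

MIN_YEAR = 1990
MAX_YEAR = 2100

#: sites must be surveyed on more than this many occasions to enter fitting
MIN_SURVEY_OCCASIONS = 3


class SchemaError(ValueError):
    """A CSV file does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a domain invariant (negative count, bad species, ...)."""


class Region(str, enum.Enum):
    """The four U.S. Pacific survey regions."""

    AMSM = "AMSM"  # American Samoa
    HIIS = "HIIS"  # Hawaiian Archipelago
    MARI = "MARI"  # Mariana Archipelago
    PRIA = "PRIA"  # Pacific Remote Island Areas


class Species(str, enum.Enum):
    GREEN = "green"
    HAWKSBILL = "hawksbill"
    UNIDENTIFIED = "unidentified"


def _parse_region(value: str) -> Region:
    try:
        return Region(str(value).strip().upper())
    except ValueError:
        raise ValidationError(f"unknown region {value!r}") from None


def _parse_species(value: str) -> Species:
    # normalized case-insensitively; anything else is an error, never coerced
    try:
        return Species(str(value).strip().lower())
    except ValueError:
        raise ValidationError(f"unknown species {value!r}") from None


@dataclass(frozen=True)
class SegmentObservation:
    """One tow segment's turtle record for one species."""

    region: Region
    site_id: str
    year: int
    tow_id: str
    segment_index: int
    segment_length_m: float
    species: Species
    count: int
    mean_length_cm: float | None = None

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise ValidationError(f"count must be a non-negative integer, got {self.count}")
        if not self.segment_length_m > 0:
            raise ValidationError(f"segment_length_m must be > 0, got {self.segment_length_m}")
        if not 1 <= self.segment_index <= 10:
            raise ValidationError(f"segment_index must be in [1, 10], got {self.segment_index}")
        if self.mean_length_cm is not None and not self.mean_length_cm > 0:
            raise ValidationError(f"mean_length_cm must be > 0, got {self.mean_length_cm}")


@dataclass(frozen=True)
class SiteMetadata:
    """Per-site survey effort summary used for density expansion."""

    site_id: str
    region: Region
    mean_segments_per_survey: float
    mean_segment_length_m: float
    n_survey_years: int

    def __post_init__(self) -> None:
        if not self.mean_segments_per_survey > 0:
            raise ValidationError("mean_segments_per_survey must be > 0")
        if not self.mean_segment_length_m > 0:
            raise ValidationError("mean_segment_length_m must be > 0")


@dataclass(frozen=True)
class DriverRecord:
    """Site-level covariates and the density response for the forest model."""

    site_id: str
    habitat_area_km2: float
    sst_c: float
    chla_mg_m3: float
    human_impact: float
    density: float

    def __post_init__(self) -> None:
        for name in ("habitat_area_km2", "chla_mg_m3", "human_impact", "density"):
            v = getattr(self, name)
            if v is None or pd.isna(v):
                raise ValidationError(f"{name} is missing for site {self.site_id}")
            if v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if self.sst_c is None or pd.isna(self.sst_c):
            raise ValidationError(f"sst_c is missing for site {self.site_id}")


SEGMENT_COLUMNS = [
    "region",
    "site_id",
    "year",
    "tow_id",
    "segment_index",
    "segment_length_m",
    "species",
    "count",
    "mean_length_cm",
]

SITE_COLUMNS = [
    "site_id",
    "region",
    "mean_segments_per_survey",
    "mean_segment_length_m",
    "n_survey_years",
]

DRIVER_COLUMNS = [
    "site_id",
    "habitat_area_km2",
    "sst_c",
    "chla_mg_m3",
    "human_impact",
    "density",
]


def nominal_segment_length_m(tow_length_m: float = 2200.0, segments_per_tow: int = 10) -> float:
    """Nominal segment length: a ~2.2 km tow split into ten 5-minute segments."""
    if segments_per_tow <= 0:
        raise ValueError("segments_per_tow must be positive")
    return tow_length_m / segments_per_tow


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_segments(path: str | Path) -> list[SegmentObservation]:
    """Read and validate a segment-observation CSV.

    Malformed rows raise :class:`ValidationError` naming the data row number
    (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype={"site_id": str, "tow_id": str})
    _require_columns(df, [c for c in SEGMENT_COLUMNS if c != "mean_length_cm"], path)
    if "mean_length_cm" not in df.columns:
        df["mean_length_cm"] = float("nan")
    records: list[SegmentObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            length = getattr(row, "mean_length_cm")
            records.append(
                SegmentObservation(
                    region=_parse_region(row.region),
                    site_id=str(row.site_id),
                    year=int(row.year),
                    tow_id=str(row.tow_id),
                    segment_index=int(row.segment_index),
                    segment_length_m=float(row.segment_length_m),
                    species=_parse_species(row.species),
                    count=int(row.count),
                    mean_length_cm=None if pd.isna(length) else float(length),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return records


def segments_to_frame(records: Iterable[SegmentObservation]) -> pd.DataFrame:
    rows = [
        {
            "region": r.region.value,
            "site_id": r.site_id,
            "year": r.year,
            "tow_id": r.tow_id,
            "segment_index": r.segment_index,
            "segment_length_m": r.segment_length_m,
            "species": r.species.value,
            "count": r.count,
            "mean_length_cm": r.mean_length_cm,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def frame_to_segments(df: pd.DataFrame) -> list[SegmentObservation]:
    return [
        SegmentObservation(
            region=_parse_region(row.region),
            site_id=str(row.site_id),
            year=int(row.year),
            tow_id=str(row.tow_id),
            segment_index=int(row.segment_index),
            segment_length_m=float(row.segment_length_m),
            species=_parse_species(row.species),
            count=int(row.count),
            mean_length_cm=None if pd.isna(row.mean_length_cm) else float(row.mean_length_cm),
        )
        for row in df.itertuples(index=False)
    ]


def write_segments(records: Iterable[SegmentObservation], path: str | Path) -> None:
    segments_to_frame(records).to_csv(path, index=False)


def read_sites(path: str | Path) -> list[SiteMetadata]:
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, SITE_COLUMNS, path)
    return [
        SiteMetadata(
            site_id=str(r.site_id),
            region=_parse_region(r.region),
            mean_segments_per_survey=float(r.mean_segments_per_survey),
            mean_segment_length_m=float(r.mean_segment_length_m),
            n_survey_years=int(r.n_survey_years),
        )
        for r in df.itertuples(index=False)
    ]


def write_sites(records: Iterable[SiteMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "region": r.region.value,
                "mean_segments_per_survey": r.mean_segments_per_survey,
                "mean_segment_length_m": r.mean_segment_length_m,
                "n_survey_years": r.n_survey_years,
            }
            for r in records
        ],
        columns=SITE_COLUMNS,
    ).to_csv(path, index=False)


def read_drivers(path: str | Path) -> list[DriverRecord]:
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, DRIVER_COLUMNS, path)
    return [
        DriverRecord(
            site_id=str(r.site_id),
            habitat_area_km2=float(r.habitat_area_km2),
            sst_c=float(r.sst_c),
            chla_mg_m3=float(r.chla_mg_m3),
            human_impact=float(r.human_impact),
            density=float(r.density),
        )
        for r in df.itertuples(index=False)
    ]


def write_drivers(records: Iterable[DriverRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records], columns=DRIVER_COLUMNS).to_csv(
        path, index=False
    )


@dataclass
class ValidationReport:
    """Report-only dataset diagnostics; validation never mutates records."""

    duplicate_keys: list[tuple[str, int, str, int, str]]
    out_of_range_years: list[int]
    sites_below_fitting_threshold: list[str]

    @property
    def clean(self) -> bool:
        return not (
            self.duplicate_keys or self.out_of_range_years or self.sites_below_fitting_threshold
        )


def validate_dataset(records: Sequence[SegmentObservation]) -> ValidationReport:
    """Flag duplicated segment keys, implausible years, and sites with too
    few survey years to support count-model fitting (fitting requires a site
    surveyed on more than two occasions)."""
    if not records:
        return ValidationReport([], [], [])
    df = segments_to_frame(records)
    key_cols = ["site_id", "year", "tow_id", "segment_index", "species"]
    dup_mask = df.duplicated(subset=key_cols, keep=False)
    duplicates = sorted(
        {tuple(row) for row in df.loc[dup_mask, key_cols].itertuples(index=False)}
    )
    bad_years = sorted(set(df.loc[(df.year < MIN_YEAR) | (df.year > MAX_YEAR), "year"]))
    years_per_site = df.groupby("site_id")["year"].nunique()
    thin_sites = sorted(years_per_site[years_per_site < MIN_SURVEY_OCCASIONS].index)
    return ValidationReport(
        duplicate_keys=list(duplicates),
        out_of_range_years=[int(y) for y in bad_years],
        sites_below_fitting_threshold=[str(s) for s in thin_sites],
    )


def segment_count_series(
    df: pd.DataFrame,
    site_id: str | None = None,
    species: str | None = None,
    year: int | None = None,
) -> pd.Series:
    """Total turtle count per tow segment, with explicit zeros.

    The full segment index is reconstructed from *all* rows (every surveyed
    segment has at least one row, even if count 0), then counts are summed
    within the requested species scope and missing segment/species cells
    filled with 0. This makes the species label on count-0 rows irrelevant.
    """
    sub = df if site_id is None else df[df.site_id == site_id]
    if year is not None:
        sub = sub[sub.year == year]
    if sub.empty:
        return pd.Series(dtype=int)
    key = ["site_id", "year", "tow_id", "segment_index"]
    all_segments = sub[key].drop_duplicates().set_index(key)
    scoped = sub if species is None else sub[sub.species == species]
    counts = scoped.groupby(key)["count"].sum()
    return counts.reindex(all_segments.index, fill_value=0).astype(int)
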