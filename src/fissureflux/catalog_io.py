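"""Reading, validating and filtering earthquake catalogs and fissure surveys.

Catalogs are CSV with a header row and columns ``event_id, year, magnitude``
plus optional ``rupture_length_km`` and ``era``. Years use astronomical
numbering (1 B.C. = 0); an ``era`` column with values ``BC``/``AD`` is
accepted as a convenience and converted (326 BC -> -325) to avoid silent
off-by-one on era arithmetic.

Survey files carry the per-fault fissure statistics with columns
``fault_name, fissure_count, length_min_m, length_max_m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import pandas as pd

from .model_config import ModelConstants

__all__ = [
    "EarthquakeEvent",
    "FissureSurveyRecord",
    "CatalogSchemaError",
    "CatalogFormatError",
    "read_catalog",
    "write_catalog",
    "read_survey",
    "write_survey",
    "filter_by_threshold",
    "packaged_survey_path",
]


class CatalogSchemaError(ValueError):
    """Required column missing or file-level structure invalid."""


class CatalogFormatError(ValueError):
    """A row failed validation; the message names the offending line."""


@dataclass(frozen=True)
class EarthquakeEvent:
    """One catalog row.

    ``year`` is the astronomical event year (may be negative),
    ``rupture_length_km`` the recorded coseismic surface-rupture length,
    absent when only the magnitude is known.
    """

    event_id: str
    year: int
    magnitude: float
    rupture_length_km: Optional[float] = None

    def __post_init__(self) -> None:
        if not 5.0 <= self.magnitude <= 9.5:
            raise CatalogFormatError(
                f"event {self.event_id}: magnitude {self.magnitude} outside [5, 9.5]"
            )
        if self.rupture_length_km is not None and not self.rupture_length_km > 0:
            raise CatalogFormatError(
                f"event {self.event_id}: rupture_length_km must be > 0, "
                f"got {self.rupture_length_km}"
            )


@dataclass(frozen=True)
class FissureSurveyRecord:
    """Per-fault fissure statistics from a post-earthquake field survey."""

    fault_name: str
    fissure_count: int
    length_min_m: float
    length_max_m: float

    def __post_init__(self) -> None:
        if self.fissure_count < 1:
            raise CatalogFormatError(
                f"fault {self.fault_name}: fissure_count must be >= 1"
            )
        if not 0 < self.length_min_m <= self.length_max_m:
            raise CatalogFormatError(
                f"fault {self.fault_name}: need 0 < length_min "
                f"({self.length_min_m}) <= length_max ({self.length_max_m})"
            )


_ERA_OFFSETS = {"AD", "BC", "CE", "BCE"}


def _to_astronomical(year: int, era: Optional[str]) -> int:
    if era is None:
        return year
    era = era.strip().upper()
    if era in ("AD", "CE"):
        return year
    if era in ("BC", "BCE"):
        return -(year - 1)
    raise CatalogFormatError(f"unknown era {era!r}; expected BC or AD")


def read_catalog(path: Union[str, Path]) -> List[EarthquakeEvent]:
    """Read an earthquake catalog CSV into validated events, order preserved."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["event_id", "year", "magnitude"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogSchemaError(
            f"catalog {path} missing required column(s): {', '.join(missing)}"
        )
    has_length = "rupture_length_km" in df.columns
    has_era = "era" in df.columns
    events: List[EarthquakeEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        raw = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            year = int(raw["year"])
        except ValueError as exc:
            raise CatalogFormatError(
                f"{path} line {line}: unparseable year {raw['year']!r}"
            ) from exc
        try:
            magnitude = float(raw["magnitude"])
        except ValueError as exc:
            raise CatalogFormatError(
                f"{path} line {line}: unparseable magnitude {raw['magnitude']!r}"
            ) from exc
        era = raw.get("era") or None if has_era else None
        length: Optional[float] = None
        if has_length and raw.get("rupture_length_km", "") != "":
            try:
                length = float(raw["rupture_length_km"])
            except ValueError as exc:
                raise CatalogFormatError(
                    f"{path} line {line}: unparseable rupture_length_km "
                    f"{raw['rupture_length_km']!r}"
                ) from exc
        try:
            events.append(
                EarthquakeEvent(
                    event_id=str(raw["event_id"]),
                    year=_to_astronomical(year, era),
                    magnitude=magnitude,
                    rupture_length_km=length,
                )
            )
        except CatalogFormatError as exc:
            raise CatalogFormatError(f"{path} line {line}: {exc}") from exc
    ids = [e.event_id for e in events]
    if len(set(ids)) != len(ids):
        warnings.warn(
            f"catalog {path} contains duplicate event_id values; "
            "historical catalogs may legitimately repeat names",
            UserWarning,
            stacklevel=2,
        )
    return events


def write_catalog(events: Sequence[EarthquakeEvent], path: Union[str, Path]) -> None:
    """Write events to CSV in the dialect :func:`read_catalog` accepts."""
    pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "year": [e.year for e in events],
            "magnitude": [e.magnitude for e in events],
            "rupture_length_km": [e.rupture_length_km for e in events],
        }
    ).to_csv(path, index=False)


def read_survey(path: Union[str, Path]) -> List[FissureSurveyRecord]:
    """Read a per-fault fissure survey CSV into validated records."""
    df = pd.read_csv(path)
    required = ["fault_name", "fissure_count", "length_min_m", "length_max_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogSchemaError(
            f"survey {path} missing required column(s): {', '.join(missing)}"
        )
    return [
        FissureSurveyRecord(
            fault_name=str(row.fault_name),
            fissure_count=int(row.fissure_count),
            length_min_m=float(row.length_min_m),
            length_max_m=float(row.length_max_m),
        )
        for row in df.itertuples(index=False)
    ]


def write_survey(records: Sequence[FissureSurveyRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "fault_name": [r.fault_name for r in records],
            "fissure_count": [r.fissure_count for r in records],
            "length_min_m": [r.length_min_m for r in records],
            "length_max_m": [r.length_max_m for r in records],
        }
    ).to_csv(path, index=False)


def filter_by_threshold(
    events: Iterable[EarthquakeEvent], constants: ModelConstants
) -> List[EarthquakeEvent]:
    """Retain events with magnitude >= the configured threshold (inclusive)."""
    return [e for e in events if e.magnitude >= constants.magnitude_threshold]


def packaged_survey_path() -> Path:
    """Path to the packaged Maduo fissure survey table (5 faults, 653 fissures)."""
    return Path(resources.files("fissureflux").joinpath("data/maduo_survey.csv"))
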