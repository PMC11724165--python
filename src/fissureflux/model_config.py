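"""Fixed constants of the fissure carbon-emission model.

Every other module is parameterized by a :class:`ModelConstants` instance so
that nothing physical is hard-coded: chamber-derived emission rates, the
assumed fissure depth, the remote-sensing healing rates, the Maduo survey
anchors used by the rupture-length scaling, the plateau area and the
reference year that defines "now".

Constants load from a flat YAML/JSON key-value file whose keys are exactly
the dataclass field names; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = [
    "ModelConstants",
    "ConfigError",
    "ConstantsValidationError",
    "load_constants",
    "save_constants",
]


class ConfigError(ValueError):
    """Malformed or inconsistent configuration input."""


class ConstantsValidationError(ConfigError):
    """A constants field violates a model invariant."""


@dataclass(frozen=True)
class ModelConstants:
    """All fixed parameters of the emission model.

    Units: emission rates in g CO2 m^-2 a^-1, lengths/depths in m, rupture
    lengths in km, areas in m^2, healing rates in m a^-1, years in
    astronomical year numbering (1 B.C. = year 0).
    """

    #: chamber-measured annual emission rate of fissure sidewalls
    sidewall_rate_Ew: float = 968.53
    #: chamber-measured annual emission rate of fissure bottoms
    bottom_rate_Eb: float = 514.79
    #: chamber-measured annual emission rate of uncracked (control) surface
    uncracked_rate: float = 1524.95
    #: assumed uniform fissure depth (carbon stock concentrated in top 3 m)
    depth_D: float = 3.0
    #: per-fissure length shrinkage rate from remote-sensing time series
    length_heal_rate_rL: float = 0.49
    #: per-fissure width widening rate (sidewall slumping)
    width_widen_rate_rW: float = 0.05
    #: representative single-fissure length (upper bound of the survey range)
    unit_fissure_length_Lprime: float = 942.0
    #: number of fissures surveyed after the Maduo earthquake
    maduo_fissure_count_NM: int = 653
    #: magnitude anchoring the Maduo rupture length when lM is not given
    maduo_magnitude: float = 7.4
    #: Maduo coseismic surface-rupture length, km; derived from
    #: maduo_magnitude via the magnitude-rupture relation when None
    maduo_rupture_length_lM: Optional[float] = None
    #: minimum magnitude retained in catalog analyses (inclusive)
    magnitude_threshold: float = 6.9
    #: area of the Qinghai-Tibet Plateau, m^2
    plateau_area: float = 2.57e12
    #: astronomical year treated as "now" for elapsed-time arithmetic
    reference_year: int = 2022

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        strictly_positive = [
            "sidewall_rate_Ew",
            "bottom_rate_Eb",
            "uncracked_rate",
            "depth_D",
            "unit_fissure_length_Lprime",
            "maduo_fissure_count_NM",
            "plateau_area",
        ]
        for name in strictly_positive:
            value = getattr(self, name)
            if not value > 0:
                raise ConstantsValidationError(
                    f"{name} must be strictly positive, got {value!r}"
                )
        # healing rates of 0 are meaningful (no healing, recovery time -> inf)
        for name in ("length_heal_rate_rL", "width_widen_rate_rW"):
            value = getattr(self, name)
            if value < 0:
                raise ConstantsValidationError(
                    f"{name} must be >= 0, got {value!r}"
                )
        if not 5.0 <= self.magnitude_threshold <= 9.5:
            raise ConstantsValidationError(
                "magnitude_threshold must be within [5, 9.5], got "
                f"{self.magnitude_threshold!r}"
            )
        if self.maduo_rupture_length_lM is not None and not self.maduo_rupture_length_lM > 0:
            raise ConstantsValidationError(
                "maduo_rupture_length_lM must be strictly positive when given, "
                f"got {self.maduo_rupture_length_lM!r}"
            )
        if not int(self.reference_year) == self.reference_year:
            raise ConstantsValidationError(
                f"reference_year must be an integer year, got {self.reference_year!r}"
            )
        if not (self.bottom_rate_Eb < self.sidewall_rate_Ew < self.uncracked_rate):
            warnings.warn(
                "emission-rate ordering Eb < Ew < uncracked violated "
                f"({self.bottom_rate_Eb}, {self.sidewall_rate_Ew}, "
                f"{self.uncracked_rate}); proceeding with user values",
                UserWarning,
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return asdict(self)


_FIELD_NAMES = {f.name for f in fields(ModelConstants)}
_INT_FIELDS = {"maduo_fissure_count_NM", "reference_year"}


def load_constants(path: Union[str, Path, None] = None) -> ModelConstants:
    """Load model constants, overlaying a flat YAML/JSON file on the defaults.

    Parameters
    ----------
    path
        Key-value config file; ``None`` returns the defaults.

    Raises
    ------
    ConfigError
        On unparseable files (with line information), unknown keys, or
        non-mapping content.
    ConstantsValidationError
        When a loaded value violates a model invariant.
    """
    if path is None:
        return ModelConstants()
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"could not parse config {path}{where}: {exc}") from exc
    if data is None:
        return ModelConstants()
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a flat key-value mapping")
    unknown = sorted(set(data) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"unknown config keys in {path}: {', '.join(unknown)}")
    coerced = {}
    for key, value in data.items():
        if value is None and key == "maduo_rupture_length_lM":
            coerced[key] = None
            continue
        try:
            coerced[key] = int(value) if key in _INT_FIELDS else float(value)
        except (TypeError, ValueError) as exc:
            raise ConstantsValidationError(
                f"config key {key} has non-numeric value {value!r}"
            ) from exc
    return ModelConstants(**coerced)


def save_constants(constants: ModelConstants, path: Union[str, Path]) -> None:
    """Write constants as flat YAML; ``load_constants`` round-trips exactly."""
    Path(path).write_text(
        yaml.safe_dump(constants.to_dict(), sort_keys=True), encoding="utf-8"
    )
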