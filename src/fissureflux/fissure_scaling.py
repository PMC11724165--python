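"""Empirical scaling chain from earthquake magnitude to fissure geometry.

The chain anchors on the 2021 Maduo earthquake field survey: the unweighted
per-fault mean of surveyed fissure-length maxima gives a representative
single-fissure length L', and L' x N_M (the surveyed fissure count) gives the
total Maduo fissure length L_M. Any other event's total fissure length scales
linearly with its coseismic surface-rupture length relative to Maduo's,

    L_k = (l_k / l_M) * L_M.

Rupture length, where not recorded in the catalog, comes from inverting the
magnitude-rupture-length regression M = 5.92 + 0.88 log10(l), with l in km
(a continental-China normal/strike-slip relation); the initial fissure width
comes from inverting the magnitude-displacement regression
M = 6.81 + 0.78 log10(W), with W in m. Base-10 logs throughout, as is
standard for seismological scaling laws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .catalog_io import EarthquakeEvent, FissureSurveyRecord
from .model_config import ConfigError, ModelConstants

__all__ = [
    "RUPTURE_INTERCEPT",
    "RUPTURE_SLOPE",
    "WIDTH_INTERCEPT",
    "WIDTH_SLOPE",
    "FissureGeometry",
    "mean_length_range",
    "maduo_total_length",
    "rupture_length_from_magnitude",
    "magnitude_from_rupture_length",
    "width_from_magnitude",
    "magnitude_from_width",
    "resolve_maduo_rupture_length",
    "total_fissure_length",
    "geometry_for_event",
]

# M = 5.92 + 0.88 log10(l_km): magnitude vs. surface-rupture length
RUPTURE_INTERCEPT = 5.92
RUPTURE_SLOPE = 0.88
# M = 6.81 + 0.78 log10(W_m): magnitude vs. average surface displacement,
# read here as the initial fissure width
WIDTH_INTERCEPT = 6.81
WIDTH_SLOPE = 0.78


@dataclass(frozen=True)
class FissureGeometry:
    """Initial fissure geometry of one earthquake, before any healing.

    ``recovery_time_a`` is the time for a representative single fissure of
    length L' to shrink to nothing at the length-healing rate.
    """

    initial_total_length_m: float
    initial_width_m: float
    rupture_length_km: float
    recovery_time_a: float

    def __post_init__(self) -> None:
        for name in ("initial_total_length_m", "initial_width_m", "rupture_length_km"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.recovery_time_a < 0:
            raise ValueError("recovery_time_a must be >= 0")


def mean_length_range(
    survey: Sequence[FissureSurveyRecord],
) -> Tuple[float, float]:
    """Unweighted per-fault means of the surveyed fissure-length minima and maxima.

    Each fault contributes equally regardless of its fissure count; the upper
    value of the returned range is the representative single-fissure length
    used to assess the maximum emission scenario.
    """
    if not survey:
        raise ValueError("survey must contain at least one fault record")
    n = len(survey)
    mean_min = sum(r.length_min_m for r in survey) / n
    mean_max = sum(r.length_max_m for r in survey) / n
    return mean_min, mean_max


def maduo_total_length(unit_fissure_length_m: float, fissure_count: int) -> float:
    """Total fissure length L_M = L' x N_M of the anchoring earthquake, m."""
    if unit_fissure_length_m <= 0 or fissure_count <= 0:
        raise ValueError("unit fissure length and count must be positive")
    return unit_fissure_length_m * fissure_count


def rupture_length_from_magnitude(magnitude: float) -> float:
    """Coseismic surface-rupture length in km from magnitude.

    Inverts M = 5.92 + 0.88 log10(l); strictly increasing in magnitude.
    """
    return 10.0 ** ((magnitude - RUPTURE_INTERCEPT) / RUPTURE_SLOPE)


def magnitude_from_rupture_length(rupture_length_km: float) -> float:
    """Forward magnitude-rupture-length relation (round-trip check)."""
    return RUPTURE_INTERCEPT + RUPTURE_SLOPE * math.log10(rupture_length_km)


def width_from_magnitude(magnitude: float) -> float:
    """Initial average fissure width in m from magnitude.

    Inverts M = 6.81 + 0.78 log10(W); strictly increasing in magnitude.
    """
    return 10.0 ** ((magnitude - WIDTH_INTERCEPT) / WIDTH_SLOPE)


def magnitude_from_width(width_m: float) -> float:
    """Forward magnitude-displacement relation (round-trip check)."""
    return WIDTH_INTERCEPT + WIDTH_SLOPE * math.log10(width_m)


def resolve_maduo_rupture_length(constants: ModelConstants) -> float:
    """Maduo rupture length l_M in km: explicit value or magnitude inversion."""
    if constants.maduo_rupture_length_lM is not None:
        return constants.maduo_rupture_length_lM
    return rupture_length_from_magnitude(constants.maduo_magnitude)


def total_fissure_length(rupture_length_km: float, constants: ModelConstants) -> float:
    """Total fissure length of an event, m: L_k = (l_k / l_M) x L_M."""
    if rupture_length_km < 0:
        raise ValueError("rupture length must be >= 0")
    l_maduo = resolve_maduo_rupture_length(constants)
    if l_maduo <= 0:
        raise ConfigError("resolved Maduo rupture length must be positive")
    l_total_maduo = maduo_total_length(
        constants.unit_fissure_length_Lprime, constants.maduo_fissure_count_NM
    )
    return rupture_length_km / l_maduo * l_total_maduo


def geometry_for_event(
    event: EarthquakeEvent, constants: ModelConstants
) -> FissureGeometry:
    """Initial fissure geometry for one above-threshold earthquake.

    A rupture length recorded in the catalog always takes precedence over the
    magnitude inversion; the initial width always comes from the magnitude.
    """
    if event.magnitude < constants.magnitude_threshold:
        raise ValueError(
            f"event {event.event_id} (M {event.magnitude}) below threshold "
            f"{constants.magnitude_threshold}; filter the catalog first"
        )
    rupture_km = (
        event.rupture_length_km
        if event.rupture_length_km is not None
        else rupture_length_from_magnitude(event.magnitude)
    )
    recovery = (
        constants.unit_fissure_length_Lprime / constants.length_heal_rate_rL
        if constants.length_heal_rate_rL > 0
        else math.inf
    )
    return FissureGeometry(
        initial_total_length_m=total_fissure_length(rupture_km, constants),
        initial_width_m=width_from_magnitude(event.magnitude),
        rupture_length_km=rupture_km,
        recovery_time_a=recovery,
    )
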