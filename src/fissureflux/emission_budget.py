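"""Annual CO2 emissions from time-averaged fissure areas.

The budget is a simple rate x area product over the two exposed surfaces,

    E = S_w * E_w + S_b * E_b      [g CO2 a^-1],

with the sidewall and bottom components reported separately, plus the
plateau-wide rate increase E / A_plateau and percentage comparisons against
user-supplied reference fluxes (the literature denominators are not bundled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence, Tuple, Union

from .healing_area import AreaBudget
from .model_config import ModelConstants

__all__ = [
    "EmissionBudget",
    "emissions_from_areas",
    "per_area_rate",
    "comparison_ratio",
    "round_half_up",
    "round_significant",
]


@dataclass(frozen=True)
class EmissionBudget:
    """Annual emission totals, g CO2 a^-1, and the plateau-wide rate increase."""

    total_g_per_a: float
    sidewall_g_per_a: float
    bottom_g_per_a: float
    rate_increase_g_per_m2_a: float

    def __post_init__(self) -> None:
        expected = self.sidewall_g_per_a + self.bottom_g_per_a
        if not math.isclose(self.total_g_per_a, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("total must equal sidewall + bottom components")


def emissions_from_areas(
    areas: AreaBudget, constants: ModelConstants
) -> EmissionBudget:
    """E = S_w E_w + S_b E_b with separately reported components."""
    sidewall = areas.sidewall_area_m2 * constants.sidewall_rate_Ew
    bottom = areas.bottom_area_m2 * constants.bottom_rate_Eb
    total = sidewall + bottom
    return EmissionBudget(
        total_g_per_a=total,
        sidewall_g_per_a=sidewall,
        bottom_g_per_a=bottom,
        rate_increase_g_per_m2_a=per_area_rate(total, constants),
    )


def per_area_rate(emission_g_per_a: float, constants: ModelConstants) -> float:
    """Emission spread over the whole plateau, g CO2 m^-2 a^-1."""
    return emission_g_per_a / constants.plateau_area


def comparison_ratio(
    emission_g_per_a: float,
    reference: Union[float, Tuple[float, float], Sequence[float]],
) -> Union[float, Tuple[float, float]]:
    """Emission as a percentage of a reference flux (or flux range).

    For a (low, high) reference range the result is the percentage range
    ordered low-to-high: dividing by the larger reference gives the smaller
    percentage.
    """
    if isinstance(reference, (tuple, list)):
        if len(reference) != 2:
            raise ValueError("reference range must have exactly two values")
        low, high = sorted(reference)
        if low <= 0:
            raise ValueError("reference fluxes must be positive")
        return (100.0 * emission_g_per_a / high, 100.0 * emission_g_per_a / low)
    if reference <= 0:
        raise ValueError("reference flux must be positive")
    return 100.0 * emission_g_per_a / reference


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at a fixed decimal place (may be negative)."""
    quantum = Decimal(f"1e{-decimals}")
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def round_significant(value: float, figures: int) -> float:
    """Round half-up to a number of significant figures (reporting precision)."""
    if value == 0:
        return 0.0
    decimals = figures - 1 - math.floor(math.log10(abs(value)))
    return round_half_up(value, decimals)
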