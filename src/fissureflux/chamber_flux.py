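"""Processing of paired control/test soil-chamber CO2 flux campaigns.

Campaigns measure efflux hourly from 08:00 to 17:00 on a closed 20 cm
collar, three replicates per timepoint, over an uncracked control surface
and test surfaces (fissure sidewall, fissure bottom, and width x depth test
fissures). Processing follows the field protocol: replicates are averaged
per timepoint, timepoints are pooled with equal weight into a campaign mean,
the mean instantaneous flux (umol CO2 m^-2 s^-1) is annualized, and each
group is expressed as a fraction of the control.

Annualization assumes the campaign mean represents the annual mean:
flux x 44.01e-6 g/umol x 31,536,000 s (365-day year). The choice is
isolated in :func:`annualize_flux` so a season-weighted alternative can be
swapped in.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import pandas as pd

__all__ = [
    "CO2_G_PER_UMOL",
    "SECONDS_PER_YEAR",
    "ANNUALIZATION_FACTOR",
    "FluxRecord",
    "GroupSummary",
    "collapse_replicates",
    "annualize_flux",
    "summarize_groups",
    "read_flux_csv",
    "write_flux_csv",
]

CO2_G_PER_UMOL = 44.01e-6
SECONDS_PER_YEAR = 365 * 24 * 3600  # 31,536,000
ANNUALIZATION_FACTOR = CO2_G_PER_UMOL * SECONDS_PER_YEAR

MEASUREMENT_HOURS = range(8, 18)  # 08:00-17:00 inclusive
MAX_REPLICATES = 3


@dataclass(frozen=True)
class FluxRecord:
    """One chamber measurement: a replicate flux at a (date, hour) timepoint."""

    campaign: str
    group: str
    date: _dt.date
    hour: int
    replicate: int
    flux_umol_m2_s: float

    def __post_init__(self) -> None:
        if self.hour not in MEASUREMENT_HOURS:
            raise ValueError(
                f"hour {self.hour} outside the 08:00-17:00 measurement window"
            )
        if self.replicate not in (1, 2, 3):
            raise ValueError(f"replicate must be 1-3, got {self.replicate}")
        if self.flux_umol_m2_s < 0:
            raise ValueError(f"flux must be >= 0, got {self.flux_umol_m2_s}")


@dataclass(frozen=True)
class GroupSummary:
    """Aggregated annual emission rate of one measurement group."""

    group: str
    n_timepoints: int
    mean_flux_umol_m2_s: float
    annual_rate_g_m2_a: float
    ratio_to_control: float


def _frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "campaign": [r.campaign for r in records],
            "group": [r.group for r in records],
            "date": [r.date for r in records],
            "hour": [r.hour for r in records],
            "replicate": [r.replicate for r in records],
            "flux": [r.flux_umol_m2_s for r in records],
        }
    )


def collapse_replicates(records: Sequence[FluxRecord]) -> pd.DataFrame:
    """Average replicates at each (date, hour) timepoint of one campaign+group.

    Returns a frame with columns ``date, hour, mean_flux, n_replicates``.
    More than three replicates at a timepoint is a protocol violation and an
    error; fewer than three is tolerated with a warning.
    """
    if not records:
        raise ValueError("no records to collapse")
    keys = {(r.campaign, r.group) for r in records}
    if len(keys) > 1:
        raise ValueError(
            f"records span multiple campaign/group combinations: {sorted(keys)}"
        )
    df = _frame(records)
    grouped = df.groupby(["date", "hour"], sort=True)["flux"].agg(["mean", "count"])
    grouped = grouped.rename(columns={"mean": "mean_flux", "count": "n_replicates"})
    if (grouped["n_replicates"] > MAX_REPLICATES).any():
        bad = grouped[grouped["n_replicates"] > MAX_REPLICATES].index[0]
        raise ValueError(
            f"timepoint {bad} has more than {MAX_REPLICATES} replicates"
        )
    if (grouped["n_replicates"] < MAX_REPLICATES).any():
        n_short = int((grouped["n_replicates"] < MAX_REPLICATES).sum())
        warnings.warn(
            f"{n_short} timepoint(s) have fewer than {MAX_REPLICATES} replicates; "
            "averaging what exists",
            UserWarning,
            stacklevel=2,
        )
    return grouped.reset_index()


def annualize_flux(mean_flux_umol_m2_s: float) -> float:
    """Convert a mean instantaneous flux to an annual rate, g CO2 m^-2 a^-1."""
    if mean_flux_umol_m2_s < 0:
        raise ValueError("flux must be >= 0")
    return mean_flux_umol_m2_s * ANNUALIZATION_FACTOR


def summarize_groups(records: Sequence[FluxRecord]) -> List[GroupSummary]:
    """Per-group campaign summaries with ratios against the control group.

    Replicates are collapsed per campaign+group; timepoints from all
    campaigns pool with equal weight into the group mean. A group labelled
    ``control`` must be present.
    """
    by_key: dict = {}
    for r in records:
        by_key.setdefault((r.campaign, r.group), []).append(r)
    groups = sorted({g for _, g in by_key})
    if "control" not in groups:
        raise ValueError("no control group present; ratios are undefined")
    pooled: dict = {}
    for (campaign, group), recs in sorted(by_key.items()):
        collapsed = collapse_replicates(recs)
        pooled.setdefault(group, []).append(collapsed)
    means = {}
    counts = {}
    for group, frames in pooled.items():
        merged = pd.concat(frames, ignore_index=True)
        means[group] = float(merged["mean_flux"].mean())
        counts[group] = int(len(merged))
    control_annual = annualize_flux(means["control"])
    summaries = []
    for group in groups:
        annual = annualize_flux(means[group])
        summaries.append(
            GroupSummary(
                group=group,
                n_timepoints=counts[group],
                mean_flux_umol_m2_s=means[group],
                annual_rate_g_m2_a=annual,
                ratio_to_control=annual / control_annual,
            )
        )
    return summaries


def read_flux_csv(path: Union[str, Path]) -> List[FluxRecord]:
    """Read chamber measurements from CSV (ISO-8601 dates)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["campaign", "group", "date", "hour", "replicate", "flux_umol_m2_s"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"flux file {path} missing required column(s): {', '.join(missing)}"
        )
    return [
        FluxRecord(
            campaign=str(row.campaign),
            group=str(row.group),
            date=_dt.date.fromisoformat(str(row.date)),
            hour=int(row.hour),
            replicate=int(row.replicate),
            flux_umol_m2_s=float(row.flux_umol_m2_s),
        )
        for row in df.itertuples(index=False)
    ]


def write_flux_csv(records: Sequence[FluxRecord], path: Union[str, Path]) -> None:
    df = _frame(records).rename(columns={"flux": "flux_umol_m2_s"})
    df["date"] = [d.isoformat() for d in df["date"]]
    df.to_csv(path, index=False)
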