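"""Wastewater-based-epidemiology aggregation: detection frequencies,
cumulative concentrations, daily loads and population-normalised loads.

Left-censored days (< LOD, < LOQ) contribute zero to all sums —
substitution at zero keeps the outputs reconcilable with the published
campaign arithmetic; no LOD/2-style alternatives are offered. A < LOQ day
still counts as a detection (the compound was seen, just not
quantifiable).

    DL   [mg/day]             = C [mg/L] × V [L/day]          (per day)
    PNDL [µg/day/1000 inh]    = DL [µg/day] / P × 1000

Per-day flows are used (not a campaign mean); the ``±`` on cumulative
quantities is the sample sd of the detected per-day values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Censor, ConcentrationValue, SchemaError, SiteDay
from .units import convert_units


@dataclass(frozen=True)
class LoadResult:
    """Campaign aggregate for one analyte."""

    analyte_name: str
    detection_frequency: int
    per_day_conc: tuple[ConcentrationValue, ...]
    cumulative_conc: float  # ng L⁻¹
    cumulative_conc_sd: Optional[float]
    cumulative_dl: float  # mg day⁻¹
    cumulative_dl_sd: Optional[float]
    cumulative_pndl: float  # µg day⁻¹ 1000 inh⁻¹
    cumulative_pndl_sd: Optional[float]


def censor_for_aggregation(v: ConcentrationValue) -> float:
    """Numeric contribution of one day: detected → value, censored → 0."""
    return float(v.value) if v.censor is Censor.DETECTED else 0.0


def detection_frequency(days: Sequence[ConcentrationValue]) -> int:
    """Number of days the compound was seen (< LOQ counts, < LOD does not)."""
    return sum(1 for v in days if v.censor is not Censor.BELOW_LOD)


def daily_load(conc_ngl: float, flow_l_day: float) -> float:
    """DL (mg day⁻¹) from an in-sample concentration and that day's flow."""
    if conc_ngl < 0 or flow_l_day < 0:
        raise ValueError("concentration and flow must be >= 0")
    conc_mgl = convert_units(conc_ngl, "ng/L", "mg/L")
    return conc_mgl * flow_l_day


def pndl(dl_mg_day: float, population: int) -> float:
    """PNDL (µg day⁻¹ 1000 inh⁻¹) from a daily load and served population."""
    if population <= 0:
        raise ValueError("population must be > 0")
    dl_ug_day = convert_units(dl_mg_day, "mg/day", "µg/day")
    return dl_ug_day / population * 1000.0


def aggregate_analyte(
    analyte_name: str,
    per_day: Sequence[ConcentrationValue],
    site_days: Sequence[SiteDay],
) -> LoadResult:
    """Aggregate one analyte's campaign into a :class:`LoadResult`.

    ``per_day`` must align one-to-one with ``site_days`` (same day order).
    """
    if len(per_day) != len(site_days):
        raise SchemaError(
            f"{analyte_name}: {len(per_day)} concentrations vs {len(site_days)} site days"
        )
    detected_concs: list[float] = []
    detected_dls: list[float] = []
    detected_pndls: list[float] = []
    cum_conc = cum_dl = cum_pndl = 0.0
    for value, day in zip(per_day, site_days):
        c = censor_for_aggregation(value)
        dl = daily_load(c, day.flow)
        pn = pndl(dl, day.population)
        cum_conc += c
        cum_dl += dl
        cum_pndl += pn
        if value.censor is Censor.DETECTED:
            detected_concs.append(c)
            detected_dls.append(dl)
            detected_pndls.append(pn)

    def _sd(xs: list[float]) -> Optional[float]:
        return float(np.std(xs, ddof=1)) if len(xs) >= 2 else (0.0 if xs else None)

    return LoadResult(
        analyte_name=analyte_name,
        detection_frequency=detection_frequency(per_day),
        per_day_conc=tuple(per_day),
        cumulative_conc=cum_conc,
        cumulative_conc_sd=_sd(detected_concs),
        cumulative_dl=cum_dl,
        cumulative_dl_sd=_sd(detected_dls),
        cumulative_pndl=cum_pndl,
        cumulative_pndl_sd=_sd(detected_pndls),
    )


def aggregate_campaign(
    concentrations: pd.DataFrame,
    site_days: Sequence[SiteDay],
) -> list[LoadResult]:
    """Aggregate a whole campaign table (columns ``analyte``, ``day``,
    ``censor``, ``value``) into per-analyte :class:`LoadResult` rows.

    Raises when a detected day has no matching site record.
    """
    by_day = {d.day_id: d for d in site_days}
    results = []
    for analyte, grp in concentrations.groupby("analyte", sort=False):
        grp = grp.sort_values("day")
        per_day: list[ConcentrationValue] = []
        days: list[SiteDay] = []
        for row in grp.itertuples():
            day = by_day.get(int(row.day))
            if day is None:
                if row.censor is Censor.DETECTED:
                    raise SchemaError(f"{analyte}: no flow record for day {row.day}")
                continue
            per_day.append(
                ConcentrationValue(
                    censor=row.censor,
                    value=float(row.value) if row.censor is Censor.DETECTED else None,
                )
            )
            days.append(day)
        results.append(aggregate_analyte(str(analyte), per_day, days))
    return results


def loads_table(results: Sequence[LoadResult]) -> pd.DataFrame:
    """Flatten :class:`LoadResult` rows into a report table."""
    return pd.DataFrame(
        [
            {
                "analyte": r.analyte_name,
                "detection_frequency": r.detection_frequency,
                "cumulative_conc": r.cumulative_conc,
                "cumulative_conc_sd": r.cumulative_conc_sd,
                "cumulative_dl": r.cumulative_dl,
                "cumulative_dl_sd": r.cumulative_dl_sd,
                "cumulative_pndl": r.cumulative_pndl,
                "cumulative_pndl_sd": r.cumulative_pndl_sd,
            }
            for r in results
        ]
    )
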