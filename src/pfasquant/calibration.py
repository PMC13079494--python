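"""Calibration fitting, back-calculation, ion-ratio and retention-time diagnostics.

Quantification is by internal-standard calibration: the response ratio
``y = quant_area / istd_area`` is regressed on nominal in-vial
concentration (µg L⁻¹) by least squares, unweighted by default with 1/x
weighting available. Replicate injections enter the fit as individual
points, preserving the triplicate design's variance structure.

The ion ratio is defined here as quantifier/qualifier area. The direction
is a convention — only consistency matters for the ±40 % identification
window, which is applied on the linear ratio around the band mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import AnalyteSpec, InsufficientDataError

logger = logging.getLogger("pfasquant")


@dataclass(frozen=True)
class InjectionRecord:
    """One injection of one analyte (integrated-peak view of a run).

    Bulk operations take DataFrames with columns matching these field
    names; this type documents the row contract and validates single rows.
    """

    sample_id: str
    analyte_name: str
    replicate_index: int
    quant_area: float
    istd_area: float
    sn_quant: float
    rt: float
    qual_area: Optional[float] = None
    sn_qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.quant_area < 0 or (self.qual_area is not None and self.qual_area < 0):
            raise ValueError("areas must be >= 0")
        if self.rt <= 0:
            raise ValueError("retention time must be > 0")


@dataclass(frozen=True)
class CalibrationFit:
    """ISTD-normalised linear response model for one analyte."""

    analyte_name: str
    slope: float
    intercept: float
    r_squared: float
    weighting: str  # "none" | "one_over_x"
    level_range: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class BackCalcResult:
    """Back-calculated in-vial concentration with range/validity flags."""

    conc: float  # µg L⁻¹; may be negative (flagged)
    extrapolated_low: bool
    extrapolated_high: bool
    negative: bool


def fit_calibration(
    records: pd.DataFrame,
    analyte: AnalyteSpec,
    weighting: str = "none",
) -> CalibrationFit:
    """Fit the calibration line for one analyte from its standard injections.

    ``records`` needs columns ``analyte``, ``level``, ``quant_area``,
    ``istd_area``; only rows inside the analyte's calibration range are
    used. Injections with zero ISTD area are excluded with a warning.
    Requires >= 3 distinct levels.
    """
    if weighting not in ("none", "one_over_x"):
        raise ValueError(f"unknown weighting {weighting!r}")
    sub = records[records["analyte"] == analyte.name]
    in_range = (sub["level"] >= analyte.calib_low) & (sub["level"] <= analyte.calib_high)
    sub = sub[in_range]
    zero_istd = sub["istd_area"] <= 0
    if zero_istd.any():
        logger.warning(
            "%s: excluding %d injections with zero ISTD area", analyte.name, int(zero_istd.sum())
        )
        sub = sub[~zero_istd]
    levels = np.asarray(sub["level"], dtype=float)
    if np.unique(levels).size < 3:
        raise InsufficientDataError(
            f"{analyte.name}: need >= 3 calibration levels, got {np.unique(levels).size}"
        )
    x = levels
    y = np.asarray(sub["quant_area"] / sub["istd_area"], dtype=float)
    w = np.ones_like(x) if weighting == "none" else 1.0 / x
    sw = np.sqrt(w)
    design = np.column_stack([x * sw, sw])
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    fitted = slope * x + intercept
    ybar = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - fitted) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(
        analyte_name=analyte.name,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        weighting=weighting,
        level_range=(float(levels.min()), float(levels.max())),
        n_points=int(len(x)),
    )


def back_calculate(fit: CalibrationFit, quant_area: float, istd_area: float) -> BackCalcResult:
    """Invert the calibration line for one injection.

    Negative concentrations are reported as computed and flagged (spike
    recovery can legitimately come out negative for compounds with
    near-zero response); values outside the fitted level range are flagged
    as extrapolated.
    """
    if fit.slope == 0:
        raise ZeroDivisionError(f"{fit.analyte_name}: calibration slope is zero")
    if istd_area <= 0:
        raise ValueError(f"{fit.analyte_name}: ISTD area must be > 0")
    ratio = quant_area / istd_area
    conc = (ratio - fit.intercept) / fit.slope
    return BackCalcResult(
        conc=conc,
        extrapolated_low=conc < fit.level_range[0],
        extrapolated_high=conc > fit.level_range[1],
        negative=conc < 0,
    )


def ion_ratio(quant_area: float, qual_area: Optional[float]) -> Optional[float]:
    """Quantifier/qualifier area ratio; ``None`` for single-transition compounds."""
    if qual_area is None or (isinstance(qual_area, float) and np.isnan(qual_area)):
        return None
    if qual_area <= 0:
        raise ValueError("qualifier area must be > 0")
    return quant_area / qual_area


@dataclass(frozen=True)
class IonRatioSummary:
    band: str  # "low" (IQL–100 µg/L) or "high" (100–1000 µg/L)
    mean: float
    sd: float
    n: int
    within_window: bool


def ion_ratio_summary(
    records: pd.DataFrame,
    band: str,
    iql: float,
    window_pct: float = 40.0,
) -> Optional[IonRatioSummary]:
    """Summarise per-injection ion ratios in one concentration band.

    Bands follow the reporting convention of splitting at 100 µg L⁻¹
    (variability is higher near the quantification limit): ``low`` covers
    IQL–100, ``high`` 100–1000. The window flag is true iff every ratio in
    the band lies within ±``window_pct`` % of the band mean. Returns
    ``None`` for an empty band or fewer than 2 usable ratios.
    """
    if band == "low":
        mask = (records["level"] >= iql) & (records["level"] <= 100.0)
    elif band == "high":
        mask = (records["level"] > 100.0) & (records["level"] <= 1000.0)
    else:
        raise ValueError(f"unknown band {band!r}")
    sub = records[mask]
    ratios = np.asarray(sub["quant_area"] / sub["qual_area"], dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < 2:
        return None
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1))
    within = bool(np.all(np.abs(ratios - mean) <= window_pct / 100.0 * abs(mean)))
    return IonRatioSummary(band=band, mean=mean, sd=sd, n=int(ratios.size), within_window=within)


def relative_retention_time(rt_analyte: float, rt_istd: float) -> float:
    """RRT = analyte RT / ISTD RT (both minutes, > 0)."""
    if rt_analyte <= 0 or rt_istd <= 0:
        raise ValueError("retention times must be > 0")
    return rt_analyte / rt_istd
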