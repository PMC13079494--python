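"""Accuracy, precision, recovery, quantification-status classification and
treatment comparisons.

Accuracy is the back-calculated over nominal concentration as a percent;
precision is the relative standard deviation (RSD = sd/mean × 100) of
replicate back-calculated concentrations; spike recovery subtracts the
unspiked (native) concentration before normalising by the spiked amount:

    Recovery (%) = (C_ss − C_us) / C_theo × 100

Recovery may exceed 100 % (matrix enhancement) or be negative (loss plus a
noisy near-zero response); both are reported as computed.

Classification bands: fully quantitative for accuracy 50–120 % and
precision < 30 %; semi-quantitative for accuracy 30–50 % or precision
30–50 %; qualitative beyond. Single-transition compounds can optionally be
capped at semi-quantitative — the cap is per-analyte because published
usage applies it to some single-transition compounds but not others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import QuantStatus, Suitability


@dataclass(frozen=True)
class ValidationMetrics:
    """Accuracy/precision/recovery for one analyte at one level and scope."""

    analyte_name: str
    level: float  # ng mL⁻¹ (numerically µg L⁻¹ in vial)
    accuracy: Optional[float]  # percent
    precision_rsd: Optional[float]  # percent
    recovery: Optional[float] = None  # percent (method scope only)
    scope: str = "intraday"  # intraday | interday | method
    c_ss: Optional[float] = None
    c_us: Optional[float] = None
    c_theo: Optional[float] = None


def accuracy(c_exp: float, c_theo: float) -> float:
    """Accuracy (%) = experimental / nominal concentration × 100."""
    if c_theo <= 0:
        raise ValueError("nominal concentration must be > 0")
    return c_exp / c_theo * 100.0


def precision(replicate_concs: Sequence[float]) -> Optional[float]:
    """Percent RSD of replicate concentrations (sample sd / mean × 100).

    Returns ``None`` (undefined) when the mean is zero; requires >= 2
    replicates.
    """
    values = np.asarray(list(replicate_concs), dtype=float)
    if values.size < 2:
        raise ValueError("precision requires >= 2 replicates")
    mean = float(values.mean())
    if mean == 0:
        return None
    return float(values.std(ddof=1)) / mean * 100.0


def recovery(c_ss: float, c_us: float, c_theo: float) -> float:
    """Spike recovery (%) = (spiked − unspiked) / nominal spike × 100."""
    if c_theo <= 0:
        raise ValueError("nominal spike concentration must be > 0")
    return (c_ss - c_us) / c_theo * 100.0


def classify_quantification(
    mean_accuracy: float,
    mean_precision: float,
    has_two_transitions: bool = True,
    enforce_transition_cap: bool = False,
) -> QuantStatus:
    """Map mean accuracy/precision (both %) to a quantification status.

    Boundary conventions (pinned by tests): quantitative needs
    50 <= accuracy <= 120 and precision < 30; the semi-quantitative
    accuracy band is [30, 50) and precision band [30, 50]. When
    ``enforce_transition_cap`` is set, an otherwise-quantitative
    single-transition compound is demoted to semi-quantitative.
    """
    in_quant_bands = 50.0 <= mean_accuracy <= 120.0 and mean_precision < 30.0
    if in_quant_bands:
        if has_two_transitions or not enforce_transition_cap:
            return QuantStatus.QUANTITATIVE
        return QuantStatus.SEMI_QUANTITATIVE
    if 30.0 <= mean_accuracy < 50.0 or 30.0 <= mean_precision <= 50.0:
        return QuantStatus.SEMI_QUANTITATIVE
    return QuantStatus.QUALITATIVE


@dataclass(frozen=True)
class TreatmentComparison:
    """Accuracy delta between a sample-handling treatment and its reference."""

    analyte_name: str
    treatment: str  # dry_down | plastic_adsorbance | elution_variant
    reference: str  # in_vial | meoh_elution
    delta_accuracy: float  # percentage points; positive = loss under treatment
    significant: bool
    suitability: Suitability


def compare_treatments(
    analyte_name: str,
    acc_treatment: float,
    sd_treatment: float,
    acc_reference: float,
    sd_reference: float,
    treatment: str = "dry_down",
    reference: str = "in_vial",
    bands: tuple[float, float] = (15.0, 30.0),
) -> TreatmentComparison:
    """Compare accuracy under a treatment against a reference preparation.

    The difference is called significant only when it falls outside the
    standard deviations of both preparations (no distributional test —
    just the sd-overlap rule). Suitability bands on the absolute delta:
    < 15 suitable, 15–30 medium, >= 30 unsuitable; assessed only when
    significant.
    """
    delta = acc_reference - acc_treatment
    significant = abs(delta) > sd_treatment and abs(delta) > sd_reference
    if not significant:
        suitability = Suitability.NOT_ASSESSED
    elif abs(delta) < bands[0]:
        suitability = Suitability.SUITABLE
    elif abs(delta) < bands[1]:
        suitability = Suitability.MEDIUM
    else:
        suitability = Suitability.UNSUITABLE
    return TreatmentComparison(
        analyte_name=analyte_name,
        treatment=treatment,
        reference=reference,
        delta_accuracy=delta,
        significant=significant,
        suitability=suitability,
    )


def summarize_levels(
    per_level: Sequence[tuple[float, float]],
) -> tuple[Optional[float], Optional[float]]:
    """Mean ± sd across per-level values, e.g. method recovery over all
    spike levels inside the calibration range. Returns (mean, sd); sd is
    NaN-free: None when fewer than 2 levels."""
    values = [v for _, v in per_level if v is not None and not math.isnan(v)]
    if not values:
        return None, None
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return mean, sd
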