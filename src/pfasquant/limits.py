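"""Instrumental (IDL/IQL) and method (MDL/MQL) limit determination.

The instrumental quantification limit (IQL) is read off replicate
calibration injections: the lowest level at which a strict majority of
injections shows a quantification trace with S/N >= 10 and a confirmation
trace with S/N >= 3.3 (the confirmation requirement is waived for
single-transition compounds). The instrumental detection limit follows as

    IDL = IQL * 3.3 / 10

i.e. the detection-versus-quantification S/N ratio; every published
IDL/IQL pair for this method satisfies IDL = IQL * 0.33 exactly.

Method limits convert instrument (in-vial, µg L⁻¹) limits to in-sample
(ng L⁻¹) limits through the method recovery and the matrix concentration
factor Cf (100 for influent wastewater):

    MQL [ng/L] = IQL [ng/L] * 100 / (Recovery[%] * Cf)

and MDL likewise from IDL. The µg→ng unit bridge is an explicit
conversion, never a fused constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .units import convert_units

logger = logging.getLogger("pfasquant")

IDL_OVER_IQL = 3.3 / 10.0  # detection vs quantification S/N thresholds

SN_QUANT_THRESHOLD = 10.0
SN_QUAL_THRESHOLD = 3.3


@dataclass(frozen=True)
class LimitSet:
    """Instrument and method limits for one analyte in one matrix."""

    analyte_name: str
    idl: Optional[float]  # µg L⁻¹ (in vial)
    iql: Optional[float]  # µg L⁻¹ (in vial)
    mdl: Optional[float]  # ng L⁻¹ (in sample)
    mql: Optional[float]  # ng L⁻¹ (in sample)
    cf: float = 100.0
    recovery_used: Optional[float] = None  # percent

    def __post_init__(self) -> None:
        if self.idl is not None and self.iql is not None and not self.idl < self.iql:
            raise ValueError(f"{self.analyte_name}: IDL must be < IQL")
        if self.mdl is not None and self.mql is not None and not self.mdl < self.mql:
            raise ValueError(f"{self.analyte_name}: MDL must be < MQL")


def determine_iql(
    records: pd.DataFrame,
    sn_quant_threshold: float = SN_QUANT_THRESHOLD,
    sn_qual_threshold: float = SN_QUAL_THRESHOLD,
    has_qualifier: bool = True,
) -> Optional[float]:
    """Lowest level at which a strict majority of injections passes both
    S/N rules.

    ``records`` needs columns ``level``, ``sn_quant`` and (when
    ``has_qualifier``) ``sn_qual``. Returns ``None`` when no level
    qualifies. Ties at exactly half the injections fail ("most
    injections" = strict majority).
    """
    if records.empty:
        return None
    sub = records.sort_values("level")
    for level, grp in sub.groupby("level", sort=True):
        ok = grp["sn_quant"] >= sn_quant_threshold
        if has_qualifier:
            ok &= grp["sn_qual"] >= sn_qual_threshold
        if int(ok.sum()) * 2 > len(grp):
            return float(level)
    return None


def derive_idl(iql: float) -> float:
    """IDL = IQL × 0.33 (the 3.3/10 detection-to-quantification S/N ratio)."""
    if iql <= 0:
        raise ValueError("IQL must be > 0")
    return iql * IDL_OVER_IQL


def method_limit(
    instr_limit_ugl: float,
    recovery_pct: Optional[float],
    cf: float = 100.0,
) -> Optional[float]:
    """Convert an instrument limit (µg L⁻¹ in vial) to a method limit
    (ng L⁻¹ in sample).

    Returns ``None`` (undefined limit) when recovery is missing or <= 0 —
    a compound that cannot be recovered from the matrix has no method
    limit.
    """
    if recovery_pct is None or recovery_pct <= 0 or pd.isna(recovery_pct):
        return None
    instr_ngl = convert_units(instr_limit_ugl, "µg/L", "ng/L")
    return instr_ngl * 100.0 / (recovery_pct * cf)


def limit_set(
    analyte_name: str,
    iql: Optional[float],
    recovery_pct: Optional[float],
    cf: float = 100.0,
) -> LimitSet:
    """Assemble the full instrument+method limit set for one analyte."""
    if iql is None:
        return LimitSet(analyte_name, None, None, None, None, cf=cf, recovery_used=recovery_pct)
    idl = derive_idl(iql)
    return LimitSet(
        analyte_name=analyte_name,
        idl=idl,
        iql=iql,
        mdl=method_limit(idl, recovery_pct, cf),
        mql=method_limit(iql, recovery_pct, cf),
        cf=cf,
        recovery_used=recovery_pct,
    )
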