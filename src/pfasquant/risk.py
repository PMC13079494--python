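"""Environmental risk quotients against the freshwater PNEC registry.

    RQ = MEC / (PNEC × dilution)

where MEC is the measured environmental concentration (here: a per-day
influent concentration, the combined-sewer-overflow worst case) and PNEC
the lowest predicted no-effect concentration in freshwater. Bands: low
(RQ < 0.1), medium (0.1 <= RQ < 1), high (RQ >= 1). A tenfold dilution
into the receiving water is a common scenario and can only lower the band.

The headline RQ per analyte uses the maximum single-day MEC — cumulative
concentrations are sums across days and are not environmental
concentrations. Display rounding is 2 significant figures; full precision
is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .model import Censor, PnecEntry, RiskBand


@dataclass(frozen=True)
class RiskResult:
    analyte_name: str
    day_id: int
    mec: float  # ng L⁻¹
    pnec: float  # ng L⁻¹
    rq: float
    band: RiskBand
    dilution_factor: float
    headline: bool = False  # True on the analyte's maximum-MEC day


def risk_quotient(mec: float, pnec: float, dilution: float = 1.0) -> float:
    """RQ = MEC / dilution / PNEC (censored days enter as MEC = 0)."""
    if pnec <= 0:
        raise ValueError("PNEC must be > 0")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if mec < 0:
        raise ValueError("MEC must be >= 0")
    return mec / dilution / pnec


def classify_risk(rq: float) -> RiskBand:
    """Half-open risk bands: low < 0.1 <= medium < 1 <= high."""
    if rq < 0:
        raise ValueError("RQ must be >= 0")
    if rq < 0.1:
        return RiskBand.LOW
    if rq < 1.0:
        return RiskBand.MEDIUM
    return RiskBand.HIGH


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (report layer only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (digits - 1))


def assess_campaign(
    concentrations: pd.DataFrame,
    pnec_registry: Sequence[PnecEntry],
    dilution: float = 1.0,
) -> list[RiskResult]:
    """Per-analyte, per-detected-day risk quotients.

    ``concentrations`` has columns ``analyte``, ``day``, ``censor``,
    ``value``. Analytes absent from the PNEC registry are not assessable
    and are skipped; censored days yield RQ = 0. The maximum-MEC day of
    each analyte is flagged as the headline value.
    """
    pnec_by_name = {e.analyte_name: e for e in pnec_registry}
    results: list[RiskResult] = []
    for analyte, grp in concentrations.groupby("analyte", sort=False):
        entry = pnec_by_name.get(str(analyte))
        if entry is None:
            continue
        day_results: list[RiskResult] = []
        for row in grp.sort_values("day").itertuples():
            mec = float(row.value) if row.censor is Censor.DETECTED else 0.0
            rq = risk_quotient(mec, entry.pnec, dilution)
            day_results.append(
                RiskResult(
                    analyte_name=str(analyte),
                    day_id=int(row.day),
                    mec=mec,
                    pnec=entry.pnec,
                    rq=rq,
                    band=classify_risk(rq),
                    dilution_factor=dilution,
                )
            )
        if day_results:
            top = max(range(len(day_results)), key=lambda i: day_results[i].mec)
            day_results[top] = RiskResult(
                **{**day_results[top].__dict__, "headline": True}
            )
        results.extend(day_results)
    return results


def risk_table(results: Sequence[RiskResult], sig_digits: int = 2) -> pd.DataFrame:
    """Report table with RQ rounded to ``sig_digits`` significant figures."""
    return pd.DataFrame(
        [
            {
                "analyte": r.analyte_name,
                "day": r.day_id,
                "mec": r.mec,
                "pnec": r.pnec,
                "dilution": r.dilution_factor,
                "rq": r.rq,
                "rq_rounded": round_sig(r.rq, sig_digits),
                "band": r.band.value,
                "headline": r.headline,
            }
            for r in results
        ]
    )


def headline_quotients(results: Sequence[RiskResult]) -> dict[str, RiskResult]:
    """Map analyte → its headline (maximum-MEC day) result."""
    return {r.analyte_name: r for r in results if r.headline}
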