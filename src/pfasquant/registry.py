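"""Registry I/O: analyte, PNEC and site-day tables, plus packaged reference data.

The package ships the published target list (MRM transitions, ISTD
assignments, calibration ranges), instrument- and method-performance tables,
the freshwater PNEC registry and a three-day influent campaign as CSV
fixtures under :mod:`pfasquant.data`, so the full reporting chain can run
without external downloads. Site flow/population records for the sampled
catchment are not published; ``site_days_synthetic.csv`` is a synthetic
stand-in with a realistic large-works flow.
"""

from __future__ import annotations

import logging
import math
from importlib.resources import files
from typing import Optional

import pandas as pd

from .model import (
    AnalyteClass,
    AnalyteSpec,
    Censor,
    ConcentrationValue,
    ExposureType,
    PnecEntry,
    QuantStatus,
    RegistryError,
    SchemaError,
    SiteDay,
    TransitionSpec,
)

logger = logging.getLogger("pfasquant")

_ANALYTE_COLUMNS = [
    "name", "analyte_class",
    "quant_precursor", "quant_product", "quant_cv", "quant_ce",
    "qual_precursor", "qual_product", "qual_cv", "qual_ce",
    "istd", "calib_low", "calib_high", "status",
]


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _num(cell: str, path, row: int, column: str) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise SchemaError(f"{path}, row {row}: malformed numeric {cell!r} in {column!r}") from None
    if math.isnan(value):
        raise SchemaError(f"{path}, row {row}: NaN in {column!r}")
    return value


def _opt_num(cell: str, path, row: int, column: str) -> Optional[float]:
    return None if cell.strip() == "" else _num(cell, path, row, column)


def load_analyte_registry(path) -> list[AnalyteSpec]:
    """Load the analyte registry, resolving ISTD links and rejecting duplicates.

    Row order is preserved. An empty file yields an empty registry with a
    warning.
    """
    df = _read_csv(path)
    if df.empty:
        logger.warning("%s: empty analyte registry", path)
        return []
    _require_columns(df, _ANALYTE_COLUMNS, path)

    specs: list[AnalyteSpec] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, after header
        name = row["name"].strip()
        if name in seen:
            raise RegistryError(f"{path}, row {rownum}: duplicate analyte {name!r}")
        seen.add(name)
        try:
            cls = AnalyteClass(row["analyte_class"].strip())
        except ValueError:
            raise RegistryError(
                f"{path}, row {rownum}: unknown analyte class {row['analyte_class']!r}"
            ) from None
        quant = TransitionSpec(
            _num(row["quant_precursor"], path, rownum, "quant_precursor"),
            _num(row["quant_product"], path, rownum, "quant_product"),
            _num(row["quant_cv"], path, rownum, "quant_cv"),
            _num(row["quant_ce"], path, rownum, "quant_ce"),
        )
        qual = None
        if row["qual_precursor"].strip() != "":
            qual = TransitionSpec(
                _num(row["qual_precursor"], path, rownum, "qual_precursor"),
                _num(row["qual_product"], path, rownum, "qual_product"),
                _num(row["qual_cv"], path, rownum, "qual_cv"),
                _num(row["qual_ce"], path, rownum, "qual_ce"),
            )
        status = QuantStatus(row["status"].strip()) if row["status"].strip() else QuantStatus.QUANTITATIVE
        istd = row["istd"].strip() or None
        specs.append(
            AnalyteSpec(
                name=name,
                analyte_class=cls,
                quant_transition=quant,
                qual_transition=qual,
                istd_name=istd,
                calib_low=_opt_num(row["calib_low"], path, rownum, "calib_low"),
                calib_high=_opt_num(row["calib_high"], path, rownum, "calib_high"),
                status=status,
            )
        )

    istds = {s.name for s in specs if s.analyte_class is AnalyteClass.ISTD}
    for spec in specs:
        if spec.analyte_class is AnalyteClass.ISTD:
            continue
        if spec.istd_name not in istds:
            raise RegistryError(
                f"{path}: analyte {spec.name!r} references unknown ISTD {spec.istd_name!r}"
            )
    return specs


def load_pnec_registry(path) -> list[PnecEntry]:
    """Load the lowest-freshwater-PNEC registry (ng L⁻¹ per analyte)."""
    df = _read_csv(path)
    _require_columns(df, ["analyte_name", "pnec"], path)
    entries = []
    for i, row in df.iterrows():
        rownum = int(i) + 2
        exposure = row.get("exposure_type", "").strip() or "unrecorded"
        entries.append(
            PnecEntry(
                analyte_name=row["analyte_name"].strip(),
                pnec=_num(row["pnec"], path, rownum, "pnec"),
                organism=row.get("organism", "").strip(),
                exposure_type=ExposureType(exposure),
            )
        )
    return entries


def load_site_days(path) -> list[SiteDay]:
    """Load per-day flow (L day⁻¹) and population records."""
    df = _read_csv(path)
    _require_columns(df, ["day_id", "flow", "population"], path)
    days = []
    for i, row in df.iterrows():
        rownum = int(i) + 2
        days.append(
            SiteDay(
                day_id=int(_num(row["day_id"], path, rownum, "day_id")),
                flow=_num(row["flow"], path, rownum, "flow"),
                population=int(_num(row["population"], path, rownum, "population")),
            )
        )
    return days


def load_influent_concentrations(path) -> pd.DataFrame:
    """Load per-day (possibly censored) influent concentrations.

    Returns a DataFrame with columns ``analyte``, ``day`` (int), ``censor``
    (:class:`~pfasquant.model.Censor`) and ``value`` (ng L⁻¹, NaN when
    censored).
    """
    df = _read_csv(path)
    _require_columns(df, ["analyte", "day", "censor", "value"], path)
    out = pd.DataFrame(
        {
            "analyte": df["analyte"].str.strip(),
            "day": df["day"].astype(int),
            "censor": df["censor"].str.strip().map(Censor),
            "value": pd.to_numeric(df["value"].replace("", None)),
        }
    )
    bad = (out["censor"] == Censor.DETECTED) != out["value"].notna()
    if bad.any():
        raise SchemaError(f"{path}: rows {list(out.index[bad])} mix censor marks and values")
    return out


def concentration_values(df: pd.DataFrame, analyte: str) -> list[ConcentrationValue]:
    """Day-ordered :class:`ConcentrationValue` list for one analyte."""
    sub = df[df["analyte"] == analyte].sort_values("day")
    return [
        ConcentrationValue(censor=c, value=(float(v) if c is Censor.DETECTED else None))
        for c, v in zip(sub["censor"], sub["value"])
    ]


# -- packaged reference tables -------------------------------------------------

def _packaged(name: str):
    return files("pfasquant.data").joinpath(name)


def packaged_analyte_registry() -> list[AnalyteSpec]:
    with _packaged("analytes.csv").open() as fh:
        return load_analyte_registry(fh)


def packaged_pnec_registry() -> list[PnecEntry]:
    with _packaged("pnec.csv").open() as fh:
        return load_pnec_registry(fh)


def packaged_site_days() -> list[SiteDay]:
    """Synthetic stand-in site records (flows/populations are not published)."""
    with _packaged("site_days_synthetic.csv").open() as fh:
        return load_site_days(fh)


def packaged_influent_days() -> pd.DataFrame:
    """Published three-day influent campaign (per-day censored concentrations)."""
    with _packaged("influent_days.csv").open() as fh:
        return load_influent_concentrations(fh)


def packaged_instrument_performance() -> pd.DataFrame:
    """Published instrument-performance table (RT, ion ratios, IDL/IQL, accuracy)."""
    with _packaged("instrument_performance.csv").open() as fh:
        return pd.read_csv(fh)


def packaged_method_performance() -> pd.DataFrame:
    """Published method-performance table (recovery, MDL/MQL, accuracy)."""
    with _packaged("method_performance.csv").open() as fh:
        return pd.read_csv(fh)


def packaged_wbe_summary() -> pd.DataFrame:
    """Published campaign summary (detection frequency, cumulative C/DL/PNDL)."""
    with _packaged("wbe_summary.csv").open() as fh:
        return pd.read_csv(fh)
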