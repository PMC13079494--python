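"""End-to-end orchestration: simulate → calibrate → limits → validate →
loads → risk, with CSV outputs and a run manifest.

The pipeline is deterministic given the configuration and seed. Outputs
carry full precision; rounding happens only in the report layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from . import limits as lim
from . import loads as wbe
from . import risk as rsk
from . import validation as val
from .model import AnalyteClass, AnalyteSpec, Censor, PnecEntry, SiteDay
from .registry import (
    load_analyte_registry,
    load_pnec_registry,
    load_site_days,
    packaged_analyte_registry,
    packaged_pnec_registry,
    packaged_site_days,
)
from .simulate import (
    AssayTruth,
    CampaignDesign,
    generate_campaign,
    generate_influent_truth,
    truth_from_registry,
)
from .units import convert_units

logger = logging.getLogger("pfasquant")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full synthetic-campaign pipeline run."""

    analytes_path: Optional[str] = None  # None → packaged registry
    pnec_path: Optional[str] = None
    site_days_path: Optional[str] = None
    weighting: str = "none"
    sn_quant_threshold: float = 10.0
    sn_qual_threshold: float = 3.3
    ion_ratio_window_pct: float = 40.0  # EPA 1633A would allow 50
    cf: float = 100.0
    dilution: float = 1.0
    seed: int = 0
    noise_cv: float = 0.05
    excluded_qc_levels: tuple[tuple[str, float], ...] = ()
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sn_quant_threshold <= 0 or self.sn_qual_threshold <= 0:
            raise ValueError("S/N thresholds must be > 0")
        if not (0 < self.ion_ratio_window_pct <= 100):
            raise ValueError("ion-ratio window must be in (0, 100]")


def _registry(config: PipelineConfig) -> list[AnalyteSpec]:
    if config.analytes_path:
        return load_analyte_registry(config.analytes_path)
    return packaged_analyte_registry()


def _pnecs(config: PipelineConfig) -> list[PnecEntry]:
    if config.pnec_path:
        return load_pnec_registry(config.pnec_path)
    return packaged_pnec_registry()


def _site_days(config: PipelineConfig) -> list[SiteDay]:
    if config.site_days_path:
        return load_site_days(config.site_days_path)
    return packaged_site_days()


def estimate_recovery_pct(
    injections: pd.DataFrame,
    fit: cal.CalibrationFit,
    analyte: AnalyteSpec,
) -> tuple[Optional[float], Optional[float], list[tuple[float, float]]]:
    """Mean ± sd method recovery across spike levels inside the calibration
    range, from matrix-spike and matrix-blank injections."""
    sub = injections[injections["analyte"] == analyte.name]
    blanks = sub[sub["sample_type"] == "matrix_blank"]
    c_us = float(
        np.mean([cal.back_calculate(fit, r.quant_area, r.istd_area).conc for r in blanks.itertuples()])
    ) if len(blanks) else 0.0
    per_level: list[tuple[float, float]] = []
    spikes = sub[sub["sample_type"] == "matrix_spike"]
    for level, grp in spikes.groupby("level"):
        if not (analyte.calib_low <= level <= analyte.calib_high):
            continue
        c_ss = float(
            np.mean([cal.back_calculate(fit, r.quant_area, r.istd_area).conc for r in grp.itertuples()])
        )
        per_level.append((float(level), val.recovery(c_ss, c_us, float(level))))
    mean, sd = val.summarize_levels(per_level)
    return mean, sd, per_level


def quantify_influent(
    injections: pd.DataFrame,
    fit: cal.CalibrationFit,
    analyte: AnalyteSpec,
    recovery_pct: Optional[float],
    limitset: lim.LimitSet,
    cf: float,
    sn_quant_threshold: float = lim.SN_QUANT_THRESHOLD,
) -> pd.DataFrame:
    """Back-calculate influent days to in-sample ng L⁻¹ and censor against
    the S/N rule and the method limits.

    A day whose quantification trace averages below the detection S/N
    (0.33 × the quantification threshold) is < LOD; between detection and
    quantification S/N it is < LOQ — this guards against false positives
    from a slightly negative calibration intercept at zero signal.
    """
    rows = []
    sub = injections[
        (injections["analyte"] == analyte.name) & (injections["sample_type"] == "influent")
    ]
    for day, grp in sub.groupby("day"):
        if recovery_pct is None or recovery_pct <= 0:
            rows.append({"analyte": analyte.name, "day": int(day), "censor": Censor.BELOW_LOD, "value": np.nan})
            continue
        mean_sn = float(np.mean(grp["sn_quant"]))
        if mean_sn < lim.IDL_OVER_IQL * sn_quant_threshold:
            rows.append({"analyte": analyte.name, "day": int(day), "censor": Censor.BELOW_LOD, "value": np.nan})
            continue
        if mean_sn < sn_quant_threshold:
            rows.append({"analyte": analyte.name, "day": int(day), "censor": Censor.BELOW_LOQ, "value": np.nan})
            continue
        vial = float(
            np.mean([cal.back_calculate(fit, r.quant_area, r.istd_area).conc for r in grp.itertuples()])
        )
        sample_ngl = convert_units(max(vial, 0.0), "µg/L", "ng/L") * 100.0 / (recovery_pct * cf)
        mdl = limitset.mdl if limitset.mdl is not None else np.inf
        mql = limitset.mql if limitset.mql is not None else np.inf
        if sample_ngl < mdl:
            rows.append({"analyte": analyte.name, "day": int(day), "censor": Censor.BELOW_LOD, "value": np.nan})
        elif sample_ngl < mql:
            rows.append({"analyte": analyte.name, "day": int(day), "censor": Censor.BELOW_LOQ, "value": np.nan})
        else:
            rows.append({"analyte": analyte.name, "day": int(day), "censor": Censor.DETECTED, "value": sample_ngl})
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    truth: Optional[AssayTruth] = None,
    design: Optional[CampaignDesign] = None,
) -> dict:
    """Run the full pipeline on a synthetic campaign.

    Returns a bundle of DataFrames (calibration fits, limits, instrument
    and method performance, influent concentrations, loads, risk) plus the
    ground-truth ledger; writes CSVs and a manifest when ``outdir`` is set.
    """
    registry = _registry(config)
    analytes = [s for s in registry if s.analyte_class is not AnalyteClass.ISTD]
    site_days = _site_days(config)
    if truth is None:
        truth = truth_from_registry(registry, noise_cv=config.noise_cv)
    if design is None:
        design = CampaignDesign(influent_days=site_days, cf=config.cf, seed=config.seed)
    assignment = {s.name: s.istd_name for s in analytes}

    # provisional method limits from truth recovery for censoring ground truth
    prior_mdl = {}
    prior_mql = {}
    for spec in analytes:
        at = truth.analytes[spec.name]
        mql = lim.method_limit(spec.calib_low, at.true_recovery * 100.0, config.cf)
        prior_mql[spec.name] = mql if mql is not None else np.inf
        mdl = lim.method_limit(lim.derive_idl(spec.calib_low), at.true_recovery * 100.0, config.cf)
        prior_mdl[spec.name] = mdl if mdl is not None else np.inf
    influent_truth = generate_influent_truth(design, truth, prior_mdl, prior_mql)
    injections, samples, ledger = generate_campaign(truth, design, influent_truth, assignment)
    ledger["config"] = config

    cal_df = injections[injections["sample_type"] == "cal"]
    qc_df = injections[injections["sample_type"] == "qc"]

    fit_rows, limit_rows, instr_rows, method_rows = [], [], [], []
    conc_frames = []
    for spec in analytes:
        fit = cal.fit_calibration(cal_df, spec, weighting=config.weighting)
        fit_rows.append({
            "analyte": spec.name, "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "weighting": fit.weighting,
            "level_low": fit.level_range[0], "level_high": fit.level_range[1],
            "n_points": fit.n_points,
        })

        iql = lim.determine_iql(
            cal_df[cal_df["analyte"] == spec.name],
            config.sn_quant_threshold,
            config.sn_qual_threshold,
            has_qualifier=spec.has_two_transitions,
        )
        rec_mean, rec_sd, per_level_rec = estimate_recovery_pct(injections, fit, spec)
        limitset = lim.limit_set(spec.name, iql, rec_mean, cf=config.cf)
        limit_rows.append({
            "analyte": spec.name, "idl": limitset.idl, "iql": limitset.iql,
            "mdl": limitset.mdl, "mql": limitset.mql,
            "cf": limitset.cf, "recovery_used": limitset.recovery_used,
        })

        # intraday accuracy/precision from mobile-phase QCs inside the range
        excluded = {lvl for name, lvl in config.excluded_qc_levels if name == spec.name}
        per_level_acc, per_level_prec = [], []
        sub_qc = qc_df[qc_df["analyte"] == spec.name]
        for level, grp in sub_qc.groupby("level"):
            if level in excluded or not (spec.calib_low <= level <= spec.calib_high):
                continue
            concs = [cal.back_calculate(fit, r.quant_area, r.istd_area).conc for r in grp.itertuples()]
            per_level_acc.append((float(level), val.accuracy(float(np.mean(concs)), float(level))))
            if len(concs) >= 2:
                rsd = val.precision(concs)
                if rsd is not None:
                    per_level_prec.append((float(level), rsd))
        acc_mean, _ = val.summarize_levels(per_level_acc)
        prec_mean, _ = val.summarize_levels(per_level_prec)
        status = (
            val.classify_quantification(acc_mean, prec_mean, spec.has_two_transitions)
            if acc_mean is not None and prec_mean is not None
            else None
        )

        ir_low = cal.ion_ratio_summary(
            cal_df[cal_df["analyte"] == spec.name], "low", iql or spec.calib_low,
            config.ion_ratio_window_pct,
        ) if spec.has_two_transitions else None
        ir_high = cal.ion_ratio_summary(
            cal_df[cal_df["analyte"] == spec.name], "high", iql or spec.calib_low,
            config.ion_ratio_window_pct,
        ) if spec.has_two_transitions else None

        instr_rows.append({
            "analyte": spec.name, "iql": iql,
            "idl": limitset.idl,
            "r_squared": fit.r_squared,
            "accuracy": acc_mean, "precision": prec_mean,
            "status": status.value if status else None,
            "ion_ratio_low": ir_low.mean if ir_low else None,
            "ion_ratio_low_sd": ir_low.sd if ir_low else None,
            "ion_ratio_low_within_window": ir_low.within_window if ir_low else None,
            "ion_ratio_high": ir_high.mean if ir_high else None,
            "ion_ratio_high_sd": ir_high.sd if ir_high else None,
            "ion_ratio_high_within_window": ir_high.within_window if ir_high else None,
        })
        method_rows.append({
            "analyte": spec.name,
            "recovery": rec_mean, "recovery_sd": rec_sd,
            "n_recovery_levels": len(per_level_rec),
            "mdl": limitset.mdl, "mql": limitset.mql,
        })

        conc_frames.append(
            quantify_influent(
                injections, fit, spec, rec_mean, limitset, config.cf,
                sn_quant_threshold=config.sn_quant_threshold,
            )
        )

    concentrations = pd.concat(conc_frames, ignore_index=True)
    load_results = wbe.aggregate_campaign(concentrations, site_days)
    risk_results = rsk.assess_campaign(concentrations, _pnecs(config), config.dilution)

    bundle = {
        "calibration_fits": pd.DataFrame(fit_rows),
        "limits": pd.DataFrame(limit_rows),
        "instrument_performance": pd.DataFrame(instr_rows),
        "method_performance": pd.DataFrame(method_rows),
        "influent_concentrations": concentrations,
        "loads": wbe.loads_table(load_results),
        "risk": rsk.risk_table(risk_results),
        "injections": injections,
        "samples": samples,
        "ledger": ledger,
    }
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in (
        "calibration_fits", "limits", "instrument_performance",
        "method_performance", "influent_concentrations", "loads", "risk",
    ):
        df = bundle[name].copy()
        for col in df.columns:
            if df[col].map(lambda v: isinstance(v, Censor)).any():
                df[col] = df[col].map(lambda v: v.value if isinstance(v, Censor) else v)
        df.to_csv(outdir / f"{name}.csv", index=False)
    cfg = dataclasses.asdict(config)
    hashed = {k: v for k, v in cfg.items() if k != "outdir"}  # hash the analytic config only
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(hashed, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "n_analytes": int(len(bundle["calibration_fits"])),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline outputs written to %s", outdir)
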