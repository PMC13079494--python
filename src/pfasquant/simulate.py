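"""Synthetic LC-MS/MS measurement-campaign generator with known ground truth.

The generator emulates the data a triple-quadrupole instrument produces
after peak integration: per-injection quantifier/qualifier areas, ISTD
areas, signal-to-noise ratios and retention times, for calibration
standards, mobile-phase QCs, spiked/unspiked wastewater-matrix samples and
influent samples. It does not simulate chromatograms (no peak shapes, no
co-elution) — the pipeline starts from integrated areas.

Noise model
-----------
Areas carry multiplicative lognormal noise (heteroscedastic; areas stay
positive), parameterised by a coefficient of variation and normalised to
unit mean so that sample means converge to truth. Quantifier area for an
injection at effective in-vial concentration ``c`` (µg L⁻¹) is::

    quant_area = response_factor * c * istd_area * noise

with the same injection's ISTD area as multiplier, so the analyte/ISTD
ratio is ``response_factor * c * noise`` — ISTD-level fluctuations cancel
in the ratio exactly as they do for a co-injected internal standard.
Matrix samples see ``c = true_recovery * (native + spike)``; influent
samples map the in-sample concentration (ng L⁻¹) to the vial via the
recovery and the concentration factor Cf.

Randomness is derived from a single campaign seed via named substreams
keyed by (analyte or ISTD, sample, replicate), so adding an analyte to the
registry does not perturb the draws of existing analytes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import AnalyteClass, AnalyteSpec, Censor, SiteDay

DEFAULT_CALIB_LEVELS: tuple[float, ...] = tuple(
    float(x) for x in np.geomspace(0.01, 1000.0, 19)
)
DEFAULT_QC_LEVELS: tuple[float, ...] = (5.0, 20.0, 200.0, 500.0)


@dataclass(frozen=True)
class AnalyteTruth:
    """Ground-truth measurement parameters for one analyte."""

    response_factor: float  # (area ratio) per µg L⁻¹
    true_recovery: float = 1.0  # fraction; may exceed 1 (matrix enhancement)
    ion_ratio_true: Optional[float] = 2.0  # None → single-transition compound
    noise_cv: float = 0.05
    sn_per_conc: float = 1000.0  # S/N per µg L⁻¹ in vial
    rt_true: float = 10.0  # minutes
    native_conc: float = 0.0  # in-sample background, ng L⁻¹
    influent_median: float = 0.0  # lognormal median of daily influent conc, ng L⁻¹
    influent_sigma: float = 0.5  # lognormal shape (log-space sd)
    influent_day_concs: Optional[tuple[float, ...]] = None  # explicit per-day truth, ng L⁻¹

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise ValueError("response_factor must be > 0")
        if not (0 <= self.noise_cv < 1):
            raise ValueError("noise_cv must be in [0, 1)")


@dataclass(frozen=True)
class IstdTruth:
    istd_area_mean: float = 1e5
    istd_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.istd_area_mean <= 0 or not (0 <= self.istd_cv < 1):
            raise ValueError("invalid ISTD truth")


@dataclass(frozen=True)
class AssayTruth:
    """Campaign-wide truth: per-analyte and per-ISTD parameters."""

    analytes: dict[str, AnalyteTruth]
    istds: dict[str, IstdTruth]


@dataclass(frozen=True)
class CampaignDesign:
    """Sampling design of a synthetic campaign (all levels in µg L⁻¹ in vial,
    numerically ng mL⁻¹)."""

    calib_levels: Sequence[float] = DEFAULT_CALIB_LEVELS
    n_injection_replicates: int = 3
    qc_levels: Sequence[float] = DEFAULT_QC_LEVELS
    spike_levels: Sequence[float] = DEFAULT_QC_LEVELS
    n_matrix_replicates: int = 3
    influent_days: Sequence[SiteDay] = ()
    cf: float = 100.0  # matrix concentration factor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("calib_levels", "qc_levels", "spike_levels"):
            levels = list(getattr(self, name))
            if levels != sorted(levels):
                raise ValueError(f"{name} must be sorted ascending")
        if self.n_injection_replicates < 1 or self.n_matrix_replicates < 1:
            raise ValueError("replicate counts must be >= 1")


def truth_from_registry(
    registry: Sequence[AnalyteSpec],
    *,
    noise_cv: float = 0.05,
    istd_cv: float = 0.05,
    true_recovery: float = 1.0,
    response_factor: float = 0.05,
) -> AssayTruth:
    """Build a plausible default truth from an analyte registry.

    Each analyte's S/N slope is anchored so that the quantifier trace hits
    S/N = 10 exactly at the low end of its calibration range, mirroring how
    the quantification limit relates to the linear range in practice.
    """
    analytes: dict[str, AnalyteTruth] = {}
    istds: dict[str, IstdTruth] = {}
    for spec in registry:
        if spec.analyte_class is AnalyteClass.ISTD:
            istds[spec.name] = IstdTruth(istd_cv=istd_cv)
            continue
        analytes[spec.name] = AnalyteTruth(
            response_factor=response_factor,
            true_recovery=true_recovery,
            ion_ratio_true=2.0 if spec.has_two_transitions else None,
            noise_cv=noise_cv,
            sn_per_conc=10.0 / spec.calib_low,
            rt_true=10.0,
        )
    return AssayTruth(analytes=analytes, istds=istds)


def zero_noise(truth: AssayTruth) -> AssayTruth:
    """Copy of ``truth`` with every noise source switched off."""
    return AssayTruth(
        analytes={k: replace(v, noise_cv=0.0) for k, v in truth.analytes.items()},
        istds={k: replace(v, istd_cv=0.0) for k, v in truth.istds.items()},
    )


def _stream(seed: int, *names) -> np.random.Generator:
    """Named substream of the campaign seed (stable across registry edits)."""
    key = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=size))


def vial_concentration(sample_conc_ngl: float, recovery_frac: float, cf: float) -> float:
    """Map an in-sample concentration (ng L⁻¹) to the in-vial concentration
    (µg L⁻¹) produced by extraction at the given fractional recovery and
    concentration factor."""
    return sample_conc_ngl * recovery_frac * cf / 1000.0


def generate_influent_truth(
    design: CampaignDesign,
    truth: AssayTruth,
    mdl: dict[str, float],
    mql: dict[str, float],
) -> pd.DataFrame:
    """Draw true per-day influent concentrations and mark censoring.

    Concentrations are lognormal with per-analyte median/shape (a median of
    0 pins the analyte at zero, i.e. absent); an explicit
    ``influent_day_concs`` tuple overrides the draw day by day. Censor
    marks compare the true concentration with the supplied method limits
    (ng L⁻¹); the returned frame keeps the uncensored truth in
    ``true_conc``.
    """
    rows = []
    for name, at in truth.analytes.items():
        rng = _stream(design.seed, "influent", name)
        for i, day in enumerate(design.influent_days):
            if at.influent_day_concs is not None:
                conc = float(at.influent_day_concs[i % len(at.influent_day_concs)])
            elif at.influent_median > 0:
                conc = float(
                    at.influent_median * np.exp(rng.normal(0.0, at.influent_sigma))
                )
            else:
                conc = 0.0
            if conc < mdl.get(name, 0.0):
                censor = Censor.BELOW_LOD
            elif conc < mql.get(name, 0.0):
                censor = Censor.BELOW_LOQ
            else:
                censor = Censor.DETECTED
            rows.append(
                {"analyte": name, "day": day.day_id, "true_conc": conc, "censor": censor}
            )
    return pd.DataFrame(rows)


def generate_campaign(
    truth: AssayTruth,
    design: CampaignDesign,
    influent_truth: Optional[pd.DataFrame] = None,
    istd_assignment: Optional[dict[str, str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the full per-injection table for a campaign.

    Returns ``(injections, samples, ledger)``: one injection row per
    sample × analyte × replicate, a sample-metadata table, and a ground-truth
    ledger (the inputs plus any influent truth). ``istd_assignment`` maps
    analyte → ISTD name; by default every analyte uses the first ISTD.
    """
    istd_names = list(truth.istds)
    if not istd_names:
        raise ValueError("truth must define at least one ISTD")
    assignment = istd_assignment or {name: istd_names[0] for name in truth.analytes}

    samples: list[dict] = []
    for level in design.calib_levels:
        samples.append({"sample_id": f"cal_{level:g}", "sample_type": "cal",
                        "level": level, "day": None, "n_replicates": design.n_injection_replicates})
    for level in design.qc_levels:
        samples.append({"sample_id": f"qc_{level:g}", "sample_type": "qc",
                        "level": level, "day": None, "n_replicates": design.n_injection_replicates})
    for level in design.spike_levels:
        samples.append({"sample_id": f"matrix_{level:g}", "sample_type": "matrix_spike",
                        "level": level, "day": None, "n_replicates": design.n_matrix_replicates})
    samples.append({"sample_id": "matrix_unspiked", "sample_type": "matrix_blank",
                    "level": 0.0, "day": None, "n_replicates": design.n_matrix_replicates})
    for day in design.influent_days:
        samples.append({"sample_id": f"influent_day{day.day_id}", "sample_type": "influent",
                        "level": None, "day": day.day_id, "n_replicates": design.n_matrix_replicates})

    influent_conc: dict[tuple[str, int], float] = {}
    if influent_truth is not None:
        influent_conc = {
            (r.analyte, int(r.day)): float(r.true_conc)
            for r in influent_truth.itertuples()
        }

    # ISTD areas drawn once per injection (shared by all analytes on that ISTD)
    istd_areas: dict[tuple[str, str, int], float] = {}
    for istd_name, it in truth.istds.items():
        for s in samples:
            rng = _stream(design.seed, "istd", istd_name, s["sample_id"])
            draws = it.istd_area_mean * _lognoise(rng, it.istd_cv, s["n_replicates"])
            for rep in range(s["n_replicates"]):
                istd_areas[(istd_name, s["sample_id"], rep)] = float(draws[rep])

    rows: list[dict] = []
    for name, at in truth.analytes.items():
        istd_name = assignment[name]
        for s in samples:
            stype = s["sample_type"]
            if stype in ("cal", "qc"):
                eff = s["level"]
            elif stype in ("matrix_spike", "matrix_blank"):
                native_vial = vial_concentration(at.native_conc, 1.0, design.cf)
                eff = at.true_recovery * (native_vial + s["level"])
            else:  # influent
                sample_conc = influent_conc.get((name, s["day"]), 0.0) + at.native_conc
                eff = vial_concentration(sample_conc, at.true_recovery, design.cf)
            rng = _stream(design.seed, "analyte", name, s["sample_id"])
            n = s["n_replicates"]
            noise_q = _lognoise(rng, at.noise_cv, n)
            noise_qual = _lognoise(rng, at.noise_cv, n)
            noise_sn = _lognoise(rng, at.noise_cv, n)
            rt_jitter = rng.normal(0.0, 0.01, n) if at.noise_cv > 0 else np.zeros(n)
            for rep in range(n):
                istd_area = istd_areas[(istd_name, s["sample_id"], rep)]
                quant_area = at.response_factor * eff * istd_area * noise_q[rep]
                if at.ion_ratio_true is not None:
                    qual_area = quant_area / at.ion_ratio_true * noise_qual[rep]
                    sn_qual = at.sn_per_conc * eff / at.ion_ratio_true * noise_sn[rep]
                else:
                    qual_area = np.nan
                    sn_qual = np.nan
                rows.append({
                    "sample_id": s["sample_id"],
                    "sample_type": stype,
                    "analyte": name,
                    "istd_name": istd_name,
                    "level": s["level"],
                    "day": s["day"],
                    "replicate": rep,
                    "quant_area": float(quant_area),
                    "qual_area": float(qual_area),
                    "istd_area": istd_area,
                    "sn_quant": float(at.sn_per_conc * eff * noise_sn[rep]),
                    "sn_qual": float(sn_qual),
                    "rt": float(at.rt_true + rt_jitter[rep]),
                })

    injections = pd.DataFrame(rows)
    samples_df = pd.DataFrame(samples)
    ledger = {
        "seed": design.seed,
        "truth": truth,
        "design": design,
        "influent_truth": influent_truth,
    }
    return injections, samples_df, ledger
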