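"""Domain types shared across the PFAS monitoring pipeline.

The pipeline quantifies per-/polyfluoroalkyl substances (PFAS) in influent
wastewater by targeted LC-MS/MS in multiple-reaction-monitoring (MRM) mode.
Each target compound is monitored on a quantifier transition and, where the
chemistry allows, a qualifier (confirmation) transition, and is quantified
against an isotopically labelled internal standard (ISTD) via the
analyte/ISTD peak-area ratio.

Unit conventions (canonical, conversions happen at I/O boundaries):

* in-vial (instrument) concentrations: µg L⁻¹ (numerically equal to ng mL⁻¹)
* in-sample (wastewater) concentrations: ng L⁻¹
* wastewater flow: L day⁻¹
* daily load (DL): mg day⁻¹
* population-normalised daily load (PNDL): µg day⁻¹ 1000 inh⁻¹
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional

logger = logging.getLogger("pfasquant")


class AnalyteClass(str, enum.Enum):
    """Chemical class of a target compound (or ISTD marker)."""

    PFSA = "PFSA"
    PFSA_PRECURSOR = "PFSA_precursor"
    PFCA = "PFCA"
    PFCA_PRECURSOR = "PFCA_precursor"
    PHOSPHONIC_PHOSPHINIC = "phosphonic_phosphinic"
    NOVEL_EMERGING = "novel_emerging"
    ISTD = "ISTD"


class QuantStatus(str, enum.Enum):
    """Quantification confidence assigned to a compound after validation."""

    QUANTITATIVE = "quantitative"
    SEMI_QUANTITATIVE = "semi_quantitative"
    QUALITATIVE = "qualitative"


class Censor(str, enum.Enum):
    """Censoring state of a reported concentration."""

    DETECTED = "detected"
    BELOW_LOQ = "below_LOQ"
    BELOW_LOD = "below_LOD"


class ExposureType(str, enum.Enum):
    ACUTE = "acute"
    CHRONIC = "chronic"
    UNRECORDED = "unrecorded"


class RiskBand(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class Suitability(str, enum.Enum):
    """Material/treatment suitability bands for accuracy loss."""

    SUITABLE = "suitable"
    MEDIUM = "medium"
    UNSUITABLE = "unsuitable"
    NOT_ASSESSED = "not_assessed"


class RegistryError(ValueError):
    """Raised when a registry file is inconsistent (e.g. dangling ISTD link)."""


class SchemaError(ValueError):
    """Raised when an input table is missing columns or has malformed cells."""


class UnitError(ValueError):
    """Raised for unsupported unit conversions."""


class InsufficientDataError(ValueError):
    """Raised when too few points/levels/replicates are available."""


@dataclass(frozen=True)
class TransitionSpec:
    """One MRM transition: precursor → product ion with cone voltage (V) and
    collision energy (eV)."""

    precursor_mz: float
    product_mz: float
    cone_voltage: float
    collision_energy: float

    def __post_init__(self) -> None:
        if not (self.precursor_mz > self.product_mz > 0):
            raise SchemaError(
                f"transition requires precursor_mz > product_mz > 0, got "
                f"{self.precursor_mz} > {self.product_mz}"
            )


@dataclass(frozen=True)
class AnalyteSpec:
    """One target compound: transitions, ISTD assignment, calibration range.

    ``calib_low``/``calib_high`` are in-vial concentrations in µg L⁻¹; the
    low end of the linear range coincides with the instrumental
    quantification limit. ISTD entries carry no calibration range of their
    own (``calib_low``/``calib_high`` are ``None``).
    """

    name: str
    analyte_class: AnalyteClass
    quant_transition: TransitionSpec
    qual_transition: Optional[TransitionSpec]
    istd_name: Optional[str]
    calib_low: Optional[float]
    calib_high: Optional[float]
    status: QuantStatus = QuantStatus.QUANTITATIVE

    def __post_init__(self) -> None:
        if self.analyte_class is AnalyteClass.ISTD:
            return
        if self.calib_low is None or self.calib_high is None:
            raise RegistryError(f"{self.name}: calibration range required")
        if not (0 < self.calib_low < self.calib_high):
            raise RegistryError(
                f"{self.name}: need 0 < calib_low < calib_high, got "
                f"({self.calib_low}, {self.calib_high})"
            )
        if not self.istd_name:
            raise RegistryError(f"{self.name}: missing ISTD assignment")
        if self.qual_transition is None and self.status is QuantStatus.QUANTITATIVE:
            # Single-transition compounds normally cap at semi-quantitative;
            # validated labels may still override (see classify_quantification).
            logger.warning(
                "%s has one transition but status 'quantitative'", self.name
            )

    @property
    def has_two_transitions(self) -> bool:
        return self.qual_transition is not None


@dataclass(frozen=True)
class PnecEntry:
    """Lowest predicted no-effect concentration (freshwater) for one analyte."""

    analyte_name: str
    pnec: float  # ng L⁻¹
    organism: str = ""
    exposure_type: ExposureType = ExposureType.UNRECORDED

    def __post_init__(self) -> None:
        if not self.pnec > 0:
            raise RegistryError(f"{self.analyte_name}: PNEC must be > 0")


@dataclass(frozen=True)
class SiteDay:
    """One sampling day at one treatment works: flow and served population."""

    day_id: int
    flow: float  # L day⁻¹
    population: int  # inhabitants

    def __post_init__(self) -> None:
        if not self.flow > 0:
            raise SchemaError(f"day {self.day_id}: flow must be > 0")
        if not (isinstance(self.population, int) and self.population > 0):
            raise SchemaError(f"day {self.day_id}: population must be a positive integer")


@dataclass(frozen=True)
class ConcentrationValue:
    """A possibly left-censored in-sample concentration (ng L⁻¹)."""

    censor: Censor
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.censor is Censor.DETECTED:
            if self.value is None or self.value < 0:
                raise SchemaError("detected concentration requires value >= 0")
        elif self.value is not None:
            raise SchemaError(f"censored value ({self.censor.value}) must not carry a number")
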