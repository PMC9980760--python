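"""Domain model: admissions, observations, scores and labels.

Plain dataclasses shared across the pipeline.  Timestamps are
:class:`datetime.datetime` throughout; laboratory units follow UK
convention (bilirubin/creatinine in µmol/L, platelets/WCC in ×10⁹/L,
PaO2 in kPa, FiO2 as a fraction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional


class InvalidInputError(ValueError):
    """Raised for physiologically impossible or malformed input."""


class AVPU(str, enum.Enum):
    """Alert / Verbal / Pain / Unresponsive consciousness scale."""

    A = "A"
    V = "V"
    P = "P"
    U = "U"


class Analyte(str, enum.Enum):
    """Laboratory analytes used by the severity scores."""

    PLATELETS = "platelets"      # ×10⁹/L
    BILIRUBIN = "bilirubin"      # µmol/L
    CREATININE = "creatinine"    # µmol/L
    WCC = "wcc"                  # ×10⁹/L
    PAO2 = "pao2"                # kPa
    FIO2 = "fio2"                # fraction


class SepsisCategory(str, enum.Enum):
    """Three-way admission classification."""

    NO_INFECTION = "no_infection"
    INFECTION_NO_SEPSIS = "infection_no_sepsis"
    SEPSIS = "sepsis"


class CultureResult(str, enum.Enum):
    """Blood-culture outcome; contaminated counts as sampled but not positive."""

    NEGATIVE = "negative"
    POSITIVE = "positive"
    CONTAMINATED = "contaminated"


@dataclass(slots=True)
class VitalsObservation:
    """One timestamped set of bedside observations; any field may be absent."""

    timestamp: datetime
    respiratory_rate: Optional[float] = None  # breaths/min
    spo2: Optional[float] = None              # %
    supplemental_oxygen: Optional[bool] = None
    temperature: Optional[float] = None       # °C
    systolic_bp: Optional[float] = None       # mmHg
    diastolic_bp: Optional[float] = None      # mmHg
    heart_rate: Optional[float] = None        # beats/min
    avpu: Optional[AVPU] = None
    gcs: Optional[int] = None                 # 3–15

    def validate(self) -> None:
        if self.spo2 is not None and not (0 <= self.spo2 <= 100):
            raise InvalidInputError(f"SpO2 {self.spo2} outside [0, 100]")
        if self.gcs is not None and not (3 <= self.gcs <= 15):
            raise InvalidInputError(f"GCS {self.gcs} outside [3, 15]")
        for name in ("respiratory_rate", "temperature", "systolic_bp",
                     "diastolic_bp", "heart_rate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidInputError(f"{name} must be non-negative, got {v}")


@dataclass(slots=True)
class LabResult:
    """One timestamped laboratory value."""

    timestamp: datetime
    analyte: Analyte
    value: float

    def validate(self) -> None:
        if self.value < 0:
            raise InvalidInputError(f"{self.analyte.value} must be >= 0")
        if self.analyte is Analyte.FIO2 and not (0.21 <= self.value <= 1.0):
            raise InvalidInputError(f"FiO2 {self.value} outside [0.21, 1.0]")


SOFA_COMPONENTS = ("respiration", "coagulation", "liver",
                   "cardiovascular", "cns", "renal")


@dataclass(slots=True)
class ScoreSet:
    """The four severity scores evaluated for one analysis window."""

    sofa_total: int = 0
    sofa_components: dict = field(
        default_factory=lambda: {c: 0 for c in SOFA_COMPONENTS})
    qsofa: int = 0
    news: int = 0
    sirs: int = 0
    evaluated_at: str = ""

    def validate(self) -> None:
        assert self.sofa_total == sum(self.sofa_components.values())
        assert all(0 <= v <= 4 for v in self.sofa_components.values())
        assert 0 <= self.qsofa <= 3
        assert 0 <= self.news <= 20
        assert 0 <= self.sirs <= 4


@dataclass(slots=True)
class WardEpisode:
    """A contiguous stay on one ward or critical-care unit."""

    ward: str
    start: datetime
    end: datetime
    critical_care: bool = False


@dataclass(slots=True)
class Antibiotic:
    timestamp: datetime
    route: str = "IV"  # oral | IV


@dataclass(slots=True)
class BloodCulture:
    timestamp: datetime
    result: CultureResult = CultureResult.NEGATIVE


@dataclass(slots=True)
class Admission:
    """One hospital stay with its linked clinical events."""

    admission_id: str
    admitted: datetime
    discharged: datetime
    patient_id: str = ""
    age: Optional[int] = None
    female: Optional[bool] = None
    simd: Optional[int] = None
    maternity: bool = False
    episodes: list[WardEpisode] = field(default_factory=list)
    vitals: list[VitalsObservation] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    antibiotics: list[Antibiotic] = field(default_factory=list)
    cultures: list[BloodCulture] = field(default_factory=list)
    icd10_codes: list[str] = field(default_factory=list)
    death_date: Optional[datetime] = None
    infection_source_documented: bool = False

    @property
    def los_hours(self) -> float:
        return (self.discharged - self.admitted).total_seconds() / 3600.0


@dataclass(slots=True)
class InfectionEpisode:
    """A qualifying infection: documented source plus at least one antibiotic."""

    admission_id: str
    onset: datetime
    source_documented: bool = True
    antibiotics: list[Antibiotic] = field(default_factory=list)


@dataclass(slots=True)
class SepsisLabel:
    """Derived Sepsis-3 classification and mortality endpoints."""

    category: SepsisCategory
    max_sofa: int = 0
    delta_sofa: int = 0
    critical_care_48h: bool = False
    analysis_scores: ScoreSet = field(default_factory=ScoreSet)
    mortality_30d_from_onset: bool = False
    mortality_30d_from_admission: bool = False
    in_hospital_death: bool = False
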