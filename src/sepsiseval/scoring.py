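"""Severity-score engines: NEWS (RCP 2012), SIRS, qSOFA and SOFA.

All four instruments follow the missing-as-normal rule: a parameter that
was not recorded contributes zero points.  Two ward-data substitutions
are built in:

* respiration (SOFA): when no arterial blood gas is available, SpO2
  replaces the PaO2/FiO2 ratio — 91–94 % scores 1, below 91 % scores 2
  (the Valik substitution);
* neurology (SOFA and qSOFA): when GCS is missing, AVPU is mapped to a
  surrogate GCS (A→15, V→13, P→8, U→3, after Zadravecz) and banded.

The surrogate GCS mapping and the kPa→mmHg conversion factor are module
constants so a deployment can override them.
"""

from __future__ import annotations

from typing import Optional

from .model import AVPU, InvalidInputError, ScoreSet, VitalsObservation

KPA_TO_MMHG = 7.50062

#: Surrogate GCS used for the SOFA/qSOFA neurological component when GCS
#: itself was never recorded.
AVPU_SURROGATE_GCS = {AVPU.A: 15, AVPU.V: 13, AVPU.P: 8, AVPU.U: 3}


# ---------------------------------------------------------------------------
# NEWS (National Early Warning Score, RCP 2012 aggregate 0–20)
# ---------------------------------------------------------------------------

def news_score(v: VitalsObservation) -> tuple[int, dict[str, int]]:
    """Aggregate NEWS with its per-parameter breakdown.

    Returns ``(total, breakdown)`` where *breakdown* maps parameter name
    to the points it contributed.  Missing parameters score 0.
    """
    v.validate()
    pts: dict[str, int] = {}

    rr = v.respiratory_rate
    if rr is not None:
        pts["respiratory_rate"] = (3 if rr <= 8 else 1 if rr < 12
                                   else 0 if rr <= 20 else 2 if rr <= 24
                                   else 3)
    spo2 = v.spo2
    if spo2 is not None:
        pts["spo2"] = 3 if spo2 <= 91 else 2 if spo2 <= 93 else 1 if spo2 <= 95 else 0
    if v.supplemental_oxygen:
        pts["supplemental_oxygen"] = 2
    t = v.temperature
    if t is not None:
        pts["temperature"] = (3 if t <= 35.0 else 1 if t <= 36.0
                              else 0 if t <= 38.0 else 1 if t <= 39.0 else 2)
    sbp = v.systolic_bp
    if sbp is not None:
        pts["systolic_bp"] = (3 if sbp <= 90 else 2 if sbp <= 100
                              else 1 if sbp <= 110 else 0 if sbp <= 219 else 3)
    hr = v.heart_rate
    if hr is not None:
        pts["heart_rate"] = (3 if hr <= 40 else 1 if hr <= 50
                             else 0 if hr <= 90 else 1 if hr <= 110
                             else 2 if hr <= 130 else 3)
    if v.avpu is not None and v.avpu is not AVPU.A:
        pts["avpu"] = 3
    return sum(pts.values()), pts


# ---------------------------------------------------------------------------
# SIRS (0–4: WCC, heart rate, respiratory rate, temperature)
# ---------------------------------------------------------------------------

def sirs_score(v: VitalsObservation, wcc: Optional[float] = None) -> int:
    """SIRS criteria count: WCC <4 or >12 ×10⁹/L, HR >90, RR >20, T <36 or >38 °C.

    Inequalities are strict; missing parameters contribute 0.
    """
    v.validate()
    if wcc is not None and wcc < 0:
        raise InvalidInputError("WCC must be non-negative")
    score = 0
    if wcc is not None and (wcc < 4 or wcc > 12):
        score += 1
    if v.heart_rate is not None and v.heart_rate > 90:
        score += 1
    if v.respiratory_rate is not None and v.respiratory_rate > 20:
        score += 1
    if v.temperature is not None and (v.temperature < 36 or v.temperature > 38):
        score += 1
    return score


# ---------------------------------------------------------------------------
# qSOFA (0–3: RR ≥22, SBP ≤100, altered mentation)
# ---------------------------------------------------------------------------

def qsofa_score(v: VitalsObservation) -> int:
    """qSOFA: RR ≥22, systolic BP ≤100 mmHg, GCS ≤13 (or AVPU below Alert).

    When GCS is absent the mentation criterion is met iff AVPU is not A.
    """
    v.validate()
    score = 0
    if v.respiratory_rate is not None and v.respiratory_rate >= 22:
        score += 1
    if v.systolic_bp is not None and v.systolic_bp <= 100:
        score += 1
    if v.gcs is not None:
        if v.gcs <= 13:
            score += 1
    elif v.avpu is not None and v.avpu is not AVPU.A:
        score += 1
    return score


# ---------------------------------------------------------------------------
# SOFA components (each 0–4, total 0–24)
# ---------------------------------------------------------------------------

def sofa_respiration_points(pao2: Optional[float] = None,
                            fio2: Optional[float] = None,
                            spo2: Optional[float] = None,
                            supplemental_oxygen: bool = False) -> int:
    """Respiratory SOFA: PaO2/FiO2 ratio when a blood gas exists, else SpO2.

    PaO2 is in kPa and converted to mmHg.  Ratio bands: <100→4, <200→3
    (both only with respiratory support, approximated by the supplemental-
    oxygen flag; without support they cap at 2), <300→2, <400→1, else 0.
    Without a blood gas, SpO2 91–94 % scores 1 and <91 % scores 2.
    """
    if fio2 is not None and not (0.21 <= fio2 <= 1.0):
        raise InvalidInputError(f"FiO2 {fio2} outside [0.21, 1.0]")
    if spo2 is not None and not (0 <= spo2 <= 100):
        raise InvalidInputError(f"SpO2 {spo2} outside [0, 100]")
    if pao2 is not None and fio2 is not None:
        ratio = pao2 * KPA_TO_MMHG / fio2
        if ratio < 100:
            return 4 if supplemental_oxygen else 2
        if ratio < 200:
            return 3 if supplemental_oxygen else 2
        if ratio < 300:
            return 2
        if ratio < 400:
            return 1
        return 0
    if spo2 is not None:
        if spo2 < 91:
            return 2
        if spo2 < 95:  # the printed 91-94% band, extended over non-integers
            return 1
        return 0
    return 0


def avpu_to_cns_points(avpu: Optional[AVPU] = None,
                       gcs: Optional[int] = None) -> int:
    """Neurological SOFA from GCS, or from AVPU via the surrogate GCS.

    GCS bands: 15→0, 13–14→1, 10–12→2, 6–9→3, <6→4.  Both absent → 0.
    """
    if gcs is None:
        if avpu is None:
            return 0
        gcs = AVPU_SURROGATE_GCS[AVPU(avpu)]
    if not (3 <= gcs <= 15):
        raise InvalidInputError(f"GCS {gcs} outside [3, 15]")
    if gcs >= 15:
        return 0
    if gcs >= 13:
        return 1
    if gcs >= 10:
        return 2
    if gcs >= 6:
        return 3
    return 4


def mean_arterial_pressure(systolic: Optional[float],
                           diastolic: Optional[float]) -> Optional[float]:
    """MAP = DBP + (SBP − DBP)/3; None unless both pressures are present."""
    if systolic is None or diastolic is None:
        return None
    return diastolic + (systolic - diastolic) / 3.0


def sofa_cardiovascular_points(map_mmhg: Optional[float],
                               vasopressor: Optional[str] = None,
                               vasopressor_dose: Optional[float] = None) -> int:
    """Cardiovascular SOFA.

    MAP <70 mmHg scores 1.  Vasopressor data (rarely charted outside
    critical care) score 2–4 when supplied: any dobutamine or dopamine
    ≤5 µg/kg/min → 2; dopamine >5 or adrenaline/noradrenaline ≤0.1 → 3;
    dopamine >15 or adrenaline/noradrenaline >0.1 → 4.  With no
    vasopressor record the component is capped at 1.
    """
    if vasopressor is not None:
        drug = vasopressor.lower()
        dose = vasopressor_dose if vasopressor_dose is not None else 0.0
        if drug == "dobutamine":
            return 2
        if drug == "dopamine":
            return 2 if dose <= 5 else 3 if dose <= 15 else 4
        if drug in ("adrenaline", "epinephrine", "noradrenaline",
                    "norepinephrine"):
            return 3 if dose <= 0.1 else 4
        raise InvalidInputError(f"unknown vasopressor {vasopressor!r}")
    if map_mmhg is not None and map_mmhg < 70:
        return 1
    return 0


def sofa_coagulation_points(platelets: Optional[float]) -> int:
    """Coagulation SOFA from platelets ×10⁹/L: <150→1, <100→2, <50→3, <20→4."""
    if platelets is None:
        return 0
    if platelets < 0:
        raise InvalidInputError("platelets must be non-negative")
    if platelets < 20:
        return 4
    if platelets < 50:
        return 3
    if platelets < 100:
        return 2
    if platelets < 150:
        return 1
    return 0


def sofa_liver_points(bilirubin: Optional[float]) -> int:
    """Liver SOFA from bilirubin µmol/L: 20–32→1, 33–101→2, 102–204→3, >204→4."""
    if bilirubin is None:
        return 0
    if bilirubin < 0:
        raise InvalidInputError("bilirubin must be non-negative")
    if bilirubin < 20:
        return 0
    if bilirubin <= 32:
        return 1
    if bilirubin <= 101:
        return 2
    if bilirubin <= 204:
        return 3
    return 4


def sofa_renal_points(creatinine: Optional[float],
                      urine_output_ml: Optional[float] = None) -> int:
    """Renal SOFA from creatinine µmol/L (110–170→1, 171–299→2, 300–440→3,
    >440→4), optionally combined with daily urine output (<500 mL→3,
    <200 mL→4); the worse of the two criteria wins."""
    pts = 0
    if creatinine is not None:
        if creatinine < 0:
            raise InvalidInputError("creatinine must be non-negative")
        pts = (0 if creatinine < 110 else 1 if creatinine <= 170
               else 2 if creatinine <= 299 else 3 if creatinine <= 440 else 4)
    if urine_output_ml is not None:
        if urine_output_ml < 200:
            pts = max(pts, 4)
        elif urine_output_ml < 500:
            pts = max(pts, 3)
    return pts


def sofa_score(worst_vitals: VitalsObservation,
               worst_labs: Optional[dict] = None,
               vasopressor: Optional[str] = None,
               vasopressor_dose: Optional[float] = None,
               urine_output_ml: Optional[float] = None,
               evaluated_at: str = "") -> ScoreSet:
    """Total SOFA from per-period worst vitals and labs.

    *worst_vitals* should hold the directionally worst value of each
    parameter over the 24 h period (lowest SpO2/BP/GCS, etc.);
    *worst_labs* maps analyte name (``platelets``, ``bilirubin``,
    ``creatinine``, ``pao2``, ``fio2``) to the period-worst value.
    Missing components score 0 and the total is the component sum.
    """
    worst_vitals.validate()
    labs = worst_labs or {}
    comp = {
        "respiration": sofa_respiration_points(
            pao2=labs.get("pao2"), fio2=labs.get("fio2"),
            spo2=worst_vitals.spo2,
            supplemental_oxygen=bool(worst_vitals.supplemental_oxygen)),
        "coagulation": sofa_coagulation_points(labs.get("platelets")),
        "liver": sofa_liver_points(labs.get("bilirubin")),
        "cardiovascular": sofa_cardiovascular_points(
            mean_arterial_pressure(worst_vitals.systolic_bp,
                                   worst_vitals.diastolic_bp),
            vasopressor, vasopressor_dose),
        "cns": avpu_to_cns_points(worst_vitals.avpu, worst_vitals.gcs),
        "renal": sofa_renal_points(labs.get("creatinine"), urine_output_ml),
    }
    return ScoreSet(sofa_total=sum(comp.values()), sofa_components=comp,
                    evaluated_at=evaluated_at)


def score_observation(v: VitalsObservation,
                      wcc: Optional[float] = None) -> dict:
    """NEWS, qSOFA and SIRS for a single observation (convenience)."""
    total, breakdown = news_score(v)
    return {"news": total, "news_breakdown": breakdown,
            "qsofa": qsofa_score(v), "sirs": sirs_score(v, wcc)}
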