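"""Sepsis-3 labelling: infection onset, acuity windows, worst-per-24h SOFA.

The analysis window is the 48 hours either side of infection onset,
split into four 24 h periods, closed on the left and open on the right:

    [onset−48h, onset−24h)  [onset−24h, onset)  [onset, onset+24h)  [onset+24h, onset+48h)

NEWS/qSOFA/SIRS are evaluated at the point of highest acuity — the
observation with the maximal NEWS inside the window (earliest wins on
ties) — and SOFA from the directionally worst value of each parameter
within each 24 h period.  Ward patients are labelled sepsis when the
maximal period SOFA is ≥2 (baseline assumed zero); patients in critical
care within 48 h of onset require a rise of ≥2 over a baseline taken
from the pre-onset periods (configurable).
"""

from __future__ import annotations

import logging
from datetime import datetime, timedelta
from typing import Optional, Sequence

from .model import (AVPU, Admission, Analyte, InfectionEpisode, InvalidInputError,
                    ScoreSet, SepsisCategory, SepsisLabel, VitalsObservation)
from .scoring import (mean_arterial_pressure, news_score, qsofa_score,
                      sirs_score, sofa_score)

log = logging.getLogger(__name__)

WINDOW_HOURS = 48
PERIOD_HOURS = 24
MORTALITY_WINDOW_HOURS = 720  # 30 days, endpoint inclusive

#: How the critical-care ΔSOFA baseline is formed from the period scores.
BASELINE_MODES = ("min_pre", "first_pre", "zero")

_AVPU_SEVERITY = {AVPU.A: 0, AVPU.V: 1, AVPU.P: 2, AVPU.U: 3}


class NoOnsetError(ValueError):
    """Infection onset is undefined: no cultures and no antibiotics."""


def infection_onset(cultures: Sequence[datetime],
                    antibiotics: Sequence[datetime]) -> datetime:
    """Onset = first blood culture or first antibiotic dose, whichever earlier."""
    events = list(cultures) + list(antibiotics)
    if not events:
        raise NoOnsetError("no blood cultures and no antibiotics: "
                           "infection onset undefined")
    return min(events)


def find_infection_episode(adm: Admission) -> Optional[InfectionEpisode]:
    """The admission's qualifying infection episode, if any.

    Infection requires a documented source and at least one antibiotic
    dose; the onset additionally considers blood-culture times.  Only the
    first qualifying episode is represented — later escalations fold into
    the same ±48 h windows.
    """
    if not adm.infection_source_documented or not adm.antibiotics:
        return None
    onset = infection_onset([c.timestamp for c in adm.cultures],
                            [a.timestamp for a in adm.antibiotics])
    return InfectionEpisode(admission_id=adm.admission_id, onset=onset,
                            antibiotics=list(adm.antibiotics))


def _in_window(t: datetime, onset: datetime) -> bool:
    dt = (t - onset).total_seconds() / 3600.0
    return -WINDOW_HOURS <= dt < WINDOW_HOURS


def _wcc_near(adm: Admission, when: datetime,
              onset: datetime) -> Optional[float]:
    """WCC result nearest in time to *when*, restricted to the window."""
    best, best_dt = None, None
    for lab in adm.labs:
        if lab.analyte is not Analyte.WCC or not _in_window(lab.timestamp, onset):
            continue
        dt = abs((lab.timestamp - when).total_seconds())
        if best_dt is None or dt < best_dt:
            best, best_dt = lab.value, dt
    return best


def highest_acuity_scores(adm: Admission, onset: datetime) -> ScoreSet:
    """NEWS/qSOFA/SIRS at the highest-NEWS observation in onset ±48 h.

    Ties on NEWS are broken by the earlier timestamp.  An empty window
    yields all-zero scores with a logged warning (missing-as-normal).
    """
    in_win = sorted((v for v in adm.vitals if _in_window(v.timestamp, onset)),
                    key=lambda v: v.timestamp)
    if not in_win:
        log.warning("admission %s: no observations within 48h of onset; "
                    "scores default to 0", adm.admission_id)
        return ScoreSet(evaluated_at="highest_acuity")
    best = max(in_win, key=lambda v: news_score(v)[0])  # max is stable: first/earliest wins ties
    wcc = _wcc_near(adm, best.timestamp, onset)
    return ScoreSet(news=news_score(best)[0], qsofa=qsofa_score(best),
                    sirs=sirs_score(best, wcc), evaluated_at="highest_acuity")


def scores_nearest_onset(adm: Admission, onset: datetime) -> ScoreSet:
    """NEWS/qSOFA/SIRS at the in-window observation closest to onset."""
    in_win = [v for v in adm.vitals if _in_window(v.timestamp, onset)]
    if not in_win:
        return ScoreSet(evaluated_at="nearest_onset")
    near = min(in_win, key=lambda v: (abs((v.timestamp - onset).total_seconds()),
                                      v.timestamp))
    wcc = _wcc_near(adm, near.timestamp, onset)
    return ScoreSet(news=news_score(near)[0], qsofa=qsofa_score(near),
                    sirs=sirs_score(near, wcc), evaluated_at="nearest_onset")


def _worst_vitals(obs: list[VitalsObservation]) -> VitalsObservation:
    """Directionally worst value of each vitals parameter over a period."""
    def vmin(attr):
        vals = [getattr(v, attr) for v in obs if getattr(v, attr) is not None]
        return min(vals) if vals else None

    # worst MAP must come from one observation's SBP/DBP pair, not
    # independent minima, which would understate the true minimum MAP
    maps = [(mean_arterial_pressure(v.systolic_bp, v.diastolic_bp), v)
            for v in obs]
    maps = [(m, v) for m, v in maps if m is not None]
    worst_pair = min(maps, key=lambda mv: mv[0])[1] if maps else None

    avpus = [v.avpu for v in obs if v.avpu is not None]
    gcss = [v.gcs for v in obs if v.gcs is not None]
    stamp = min(v.timestamp for v in obs)
    return VitalsObservation(
        timestamp=stamp,
        spo2=vmin("spo2"),
        systolic_bp=worst_pair.systolic_bp if worst_pair else vmin("systolic_bp"),
        diastolic_bp=worst_pair.diastolic_bp if worst_pair else None,
        supplemental_oxygen=any(bool(v.supplemental_oxygen) for v in obs),
        avpu=max(avpus, key=_AVPU_SEVERITY.get) if avpus else None,
        gcs=min(gcss) if gcss else None,
    )


def _worst_labs(labs: list) -> dict:
    out: dict[str, float] = {}
    for lab in labs:
        k = lab.analyte.value
        if k in ("platelets", "pao2"):
            out[k] = min(out.get(k, lab.value), lab.value)
        elif k in ("bilirubin", "creatinine", "fio2"):
            out[k] = max(out.get(k, lab.value), lab.value)
    return out


def worst_sofa_by_period(adm: Admission, onset: datetime) -> list[ScoreSet]:
    """SOFA per 24 h period from period-worst vitals and labs (4 periods)."""
    out: list[ScoreSet] = []
    for i in range(4):
        start = onset + timedelta(hours=-WINDOW_HOURS + i * PERIOD_HOURS)
        end = start + timedelta(hours=PERIOD_HOURS)
        obs = [v for v in adm.vitals if start <= v.timestamp < end]
        labs = [l for l in adm.labs if start <= l.timestamp < end]
        name = f"period_{i + 1}"
        if not obs and not labs:
            out.append(ScoreSet(evaluated_at=name))
            continue
        worst_v = (_worst_vitals(obs) if obs
                   else VitalsObservation(timestamp=start))
        out.append(sofa_score(worst_v, _worst_labs(labs), evaluated_at=name))
    return out


def in_critical_care_48h(adm: Admission, onset: datetime) -> bool:
    """True when any critical-care episode overlaps onset ±48 h."""
    lo = onset - timedelta(hours=WINDOW_HOURS)
    hi = onset + timedelta(hours=WINDOW_HOURS)
    return any(ep.critical_care and ep.start < hi and ep.end > lo
               for ep in adm.episodes)


def delta_sofa(sofa_by_period: Sequence[ScoreSet],
               baseline_mode: str = "min_pre") -> tuple[int, int]:
    """(max period SOFA, rise over baseline) for the critical-care rule.

    ``min_pre``: baseline is the smaller of the two pre-onset period
    scores (empty periods count 0); ``first_pre``: the earliest pre-onset
    period; ``zero``: baseline 0, making the rise equal the maximum.
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"baseline_mode must be one of {BASELINE_MODES}")
    totals = [s.sofa_total for s in sofa_by_period]
    max_sofa = max(totals)
    if baseline_mode == "zero":
        baseline = 0
    elif baseline_mode == "first_pre":
        baseline = totals[0]
    else:
        baseline = min(totals[0], totals[1])
    return max_sofa, max_sofa - baseline


def mortality_endpoints(adm: Admission,
                        onset: Optional[datetime]) -> tuple[bool, bool, bool]:
    """(30 d from onset, 30 d from admission, in-hospital) death indicators.

    The 30-day windows are inclusive of the day-30 timestamp (+720 h).
    """
    d = adm.death_date
    if d is None:
        return False, False, False
    if d < adm.admitted:
        raise InvalidInputError(
            f"admission {adm.admission_id}: death before admission")
    win = timedelta(hours=MORTALITY_WINDOW_HOURS)
    from_onset = onset is not None and d <= onset + win
    from_admission = d <= adm.admitted + win
    in_hospital = d <= adm.discharged
    return from_onset, from_admission, in_hospital


def classify_sepsis(adm: Admission,
                    baseline_mode: str = "min_pre") -> SepsisLabel:
    """Full Sepsis-3 label for one admission.

    No qualifying infection → ``no_infection``.  Otherwise sepsis is
    max SOFA ≥2 on the ward, or a ΔSOFA ≥2 for patients in critical care
    within 48 h of onset, over the four 24 h periods around onset.
    """
    episode = find_infection_episode(adm)
    if episode is None:
        _, m_adm, m_hosp = mortality_endpoints(adm, None)
        return SepsisLabel(category=SepsisCategory.NO_INFECTION,
                           mortality_30d_from_admission=m_adm,
                           in_hospital_death=m_hosp)
    onset = episode.onset
    periods = worst_sofa_by_period(adm, onset)
    cc = in_critical_care_48h(adm, onset)
    max_sofa, delta = delta_sofa(periods, baseline_mode)
    septic = (delta >= 2) if cc else (max_sofa >= 2)
    m_onset, m_adm, m_hosp = mortality_endpoints(adm, onset)
    return SepsisLabel(
        category=SepsisCategory.SEPSIS if septic
        else SepsisCategory.INFECTION_NO_SEPSIS,
        max_sofa=max_sofa, delta_sofa=delta, critical_care_48h=cc,
        analysis_scores=highest_acuity_scores(adm, onset),
        mortality_30d_from_onset=m_onset,
        mortality_30d_from_admission=m_adm,
        in_hospital_death=m_hosp)
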