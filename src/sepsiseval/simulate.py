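"""Synthetic EHR cohort generator, eligibility filters and culture matching.

The generator emulates the statistical structure of a matched, infection-
enriched hospital cohort: 65.7 % of admissions treated for infection,
55.1 % of those meeting Sepsis-3 criteria, with category-conditional
30-day mortality, blood-culture sampling/positivity, ICD-10 coding
probabilities and length of stay.  Each admission carries its latent
truth (``true_category``, ``true_onset``) so recovery of the generative
parameters by the scoring → labelling → surveillance pipeline can be
checked end to end.

Vitals follow a deliberately simple generative model: per-admission
Gaussian baselines with small between-observation noise, plus a
category-conditional perturbation that peaks at infection onset and
decays exponentially over ~24 h.  Laboratory panels are drawn daily with
an analogous day-level perturbation.  Putting most of the variance in
the per-admission random effect (rather than observation noise) keeps
the worst-value-per-24h aggregation from manufacturing spurious organ
failure in mildly ill patients.

Randomness is organised as one named substream per data domain, all
derived from a single seed, so extending one component of the generator
never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .model import (AVPU, Admission, Analyte, Antibiotic, BloodCulture,
                    CultureResult, LabResult, SepsisCategory, VitalsObservation,
                    WardEpisode)

_CAT = (SepsisCategory.SEPSIS, SepsisCategory.INFECTION_NO_SEPSIS,
        SepsisCategory.NO_INFECTION)

_STREAMS = ("category", "times", "vitals", "labs", "micro", "coding",
            "mortality", "wards", "readmission")


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters; the defaults are the study conditions.

    Proportions are per latent category (sepsis / infection without
    sepsis / no infection) where given as mappings.
    """

    n_admissions: int = 958
    seed: int = 0
    infection_prevalence: float = 0.657
    sepsis_given_infection: float = 0.551
    #: P(death within 30 days of admission | category)
    mortality_30d: dict = field(default_factory=lambda: {
        "sepsis": 0.199, "infection_no_sepsis": 0.053, "no_infection": 0.040})
    #: P(any blood culture sampled | category)
    culture_sampling: dict = field(default_factory=lambda: {
        "sepsis": 0.660, "infection_no_sepsis": 0.703, "no_infection": 0.155})
    #: P(positive culture | sampled, category)
    culture_positive_given_sampled: dict = field(default_factory=lambda: {
        "sepsis": 0.114, "infection_no_sepsis": 0.080, "no_infection": 0.0})
    #: P(contaminant growth | sampled and not positive)
    culture_contaminated_given_sampled: float = 0.05
    #: P(≥1 infection ICD-10 code | category)
    infection_code_prob: dict = field(default_factory=lambda: {
        "sepsis": 0.651, "infection_no_sepsis": 0.550, "no_infection": 0.130})
    #: P(≥1 explicit sepsis ICD-10 code | category)
    sepsis_code_prob: dict = field(default_factory=lambda: {
        "sepsis": 0.078, "infection_no_sepsis": 0.035, "no_infection": 0.015})
    #: P(critical care within 48 h of onset | infected category);
    #: for uninfected admissions, P(any critical-care episode).
    critical_care_prob: dict = field(default_factory=lambda: {
        "sepsis": 0.133, "infection_no_sepsis": 0.046, "no_infection": 0.067})
    #: median length of stay in days, per category (log-normal, σ=0.75)
    los_median_days: dict = field(default_factory=lambda: {
        "sepsis": 5.8, "infection_no_sepsis": 3.9, "no_infection": 3.8})
    los_sigma: float = 0.75
    #: observation cadence bounds, hours
    obs_interval_h: tuple = (4.0, 8.0)
    #: vitals horizon: observations generated for the first N days of stay
    vitals_horizon_days: float = 8.0
    maternity_rate: float = 0.0
    short_stay_rate: float = 0.0   # admissions under 24 h (filter fodder)
    readmission_rate: float = 0.03
    n_wards: int = 8
    start: datetime = datetime(2015, 10, 1)
    study_days: int = 182

    def validate(self) -> None:
        if self.n_admissions < 2:
            raise ValueError("n_admissions must be >= 2")
        props = [self.infection_prevalence, self.sepsis_given_infection,
                 self.maternity_rate, self.short_stay_rate,
                 self.readmission_rate,
                 self.culture_contaminated_given_sampled]
        for m in (self.mortality_30d, self.culture_sampling,
                  self.culture_positive_given_sampled,
                  self.infection_code_prob, self.sepsis_code_prob,
                  self.critical_care_prob):
            props.extend(m.values())
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ValueError("all proportions must lie in [0, 1]")


@dataclass(slots=True)
class SyntheticAdmission(Admission):
    """Admission plus the generator's latent truth."""

    true_category: SepsisCategory = SepsisCategory.NO_INFECTION
    true_onset: Optional[datetime] = None


# per-admission baseline means/SDs and observation noise SDs
_BASELINES = {
    "respiratory_rate": (16.0, 1.5, 0.8),
    "spo2": (96.8, 0.8, 0.4),
    "temperature": (36.7, 0.30, 0.15),
    "systolic_bp": (128.0, 10.0, 4.0),
    "diastolic_bp": (74.0, 6.0, 3.0),
    "heart_rate": (78.0, 8.0, 4.0),
}

# peak perturbation at infection onset, by infected category
_VITAL_EFFECTS = {
    SepsisCategory.SEPSIS: {
        "respiratory_rate": 8.5, "spo2": -4.3, "temperature": 1.7,
        "systolic_bp": -32.0, "diastolic_bp": -16.0, "heart_rate": 34.0},
    SepsisCategory.INFECTION_NO_SEPSIS: {
        "respiratory_rate": 4.5, "spo2": -0.5, "temperature": 1.1,
        "systolic_bp": -6.0, "diastolic_bp": -4.0, "heart_rate": 14.0},
}

# lab baselines (mean, per-admission SD, day-level SD)
_LAB_BASE = {
    Analyte.PLATELETS: (255.0, 45.0, 8.0),
    Analyte.BILIRUBIN: (9.0, 3.0, 1.0),
    Analyte.CREATININE: (76.0, 14.0, 4.0),
    Analyte.WCC: (7.5, 1.5, 0.6),
}

# peak day-level perturbation by infected category
_LAB_EFFECTS = {
    SepsisCategory.SEPSIS: {
        Analyte.PLATELETS: -165.0, Analyte.BILIRUBIN: 38.0,
        Analyte.CREATININE: 105.0, Analyte.WCC: 9.0},
    SepsisCategory.INFECTION_NO_SEPSIS: {
        Analyte.PLATELETS: -10.0, Analyte.BILIRUBIN: 2.0,
        Analyte.CREATININE: 6.0, Analyte.WCC: 5.0},
}

_SEPSIS_CODES = ("A41.9", "A41.5", "A40.0", "R57.2")
_INFECTION_CODES = ("J18.9", "J18.1", "J15.9", "J22", "N39.0", "N10",
                    "A09", "L03.1", "B96.2", "K81.0")
_NOISE_CODES = ("I10", "E11.9", "I25.1", "I48", "N17.9", "E87.6", "J44.9",
                "K59.0", "Z50.1", "F05.9", "M79.6", "C34.9")

_VITAL_DECAY_H = 24.0
_LAB_DECAY_H = 36.0


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(_STREAMS, children)}


def _draw_category(rng: np.random.Generator, p: CohortParams) -> SepsisCategory:
    if rng.random() >= p.infection_prevalence:
        return SepsisCategory.NO_INFECTION
    return (SepsisCategory.SEPSIS
            if rng.random() < p.sepsis_given_infection
            else SepsisCategory.INFECTION_NO_SEPSIS)


def _draw_los_hours(rng: np.random.Generator, p: CohortParams,
                    cat: SepsisCategory, short_stay: bool) -> float:
    if short_stay:
        return float(rng.uniform(4.0, 23.0))
    med = p.los_median_days[cat.value] * 24.0
    los = float(np.exp(rng.normal(math.log(med), p.los_sigma)))
    return float(np.clip(los, 26.0, 45 * 24.0))


def _make_vitals(rng: np.random.Generator, p: CohortParams, adm_start: datetime,
                 los_h: float, cat: SepsisCategory, onset_h: Optional[float],
                 severity: float, cc_48h: bool) -> list[VitalsObservation]:
    horizon = min(los_h, p.vitals_horizon_days * 24.0)
    t, times = 0.0, []
    while t < horizon:
        times.append(t)
        t += float(rng.uniform(*p.obs_interval_h))
    if not times:
        times = [max(0.0, los_h / 2.0)]
    th = np.asarray(times)

    infected = cat is not SepsisCategory.NO_INFECTION
    if infected and onset_h is not None:
        decay = np.exp(-np.abs(th - onset_h) / _VITAL_DECAY_H)
        eff_scale = (1.0 + 0.18 * (severity - 1.0)) * decay
    else:
        eff_scale = np.zeros_like(th)

    cols: dict[str, np.ndarray] = {}
    for name, (mu, sd_adm, sd_obs) in _BASELINES.items():
        base = rng.normal(mu, sd_adm)
        vals = base + rng.normal(0.0, sd_obs, size=len(th))
        if infected:
            vals = vals + _VITAL_EFFECTS[cat][name] * eff_scale
        cols[name] = vals
    cols["spo2"] = np.clip(cols["spo2"], 60.0, 100.0)
    cols["respiratory_rate"] = np.clip(cols["respiratory_rate"], 6.0, 60.0)
    cols["systolic_bp"] = np.clip(cols["systolic_bp"], 55.0, 240.0)
    cols["diastolic_bp"] = np.minimum(
        np.clip(cols["diastolic_bp"], 30.0, 140.0), cols["systolic_bp"] - 10.0)
    cols["heart_rate"] = np.clip(cols["heart_rate"], 30.0, 190.0)

    # consciousness and oxygen: category-conditional, only near onset
    near = eff_scale > 0.5
    if cat is SepsisCategory.SEPSIS:
        p_avpu = np.where(near, 0.27, 0.02)
        p_o2 = np.where(near, 0.50, 0.05)
    elif cat is SepsisCategory.INFECTION_NO_SEPSIS:
        # kept low: the per-period worst-value aggregation spans ~18
        # observations, so even rare AVPU drops inflate the CNS component
        p_avpu = np.where(near, 0.012, 0.004)
        p_o2 = np.where(near, 0.12, 0.02)
    else:
        p_avpu = np.full(len(th), 0.004)
        p_o2 = np.full(len(th), 0.02)
    altered = rng.random(len(th)) < p_avpu
    on_o2 = rng.random(len(th)) < p_o2
    gcs_recorded = rng.random(len(th)) < 0.26

    out = []
    for i, hours in enumerate(times):
        if altered[i]:
            avpu = AVPU.V if rng.random() < 0.8 else (
                AVPU.P if rng.random() < 0.8 else AVPU.U)
        else:
            avpu = AVPU.A
        gcs = None
        if gcs_recorded[i]:
            gcs = {AVPU.A: 15, AVPU.V: 13, AVPU.P: 8, AVPU.U: 3}[avpu]
            if avpu is AVPU.V and rng.random() < 0.5:
                gcs = 14
        out.append(VitalsObservation(
            timestamp=adm_start + timedelta(hours=hours),
            respiratory_rate=round(float(cols["respiratory_rate"][i])),
            spo2=round(float(cols["spo2"][i])),
            supplemental_oxygen=bool(on_o2[i]),
            temperature=round(float(cols["temperature"][i]), 1),
            systolic_bp=round(float(cols["systolic_bp"][i])),
            diastolic_bp=round(float(cols["diastolic_bp"][i])),
            heart_rate=round(float(cols["heart_rate"][i])),
            avpu=avpu, gcs=gcs))
    return out


def _make_labs(rng: np.random.Generator, p: CohortParams, adm_start: datetime,
               los_h: float, cat: SepsisCategory, onset_h: Optional[float],
               cc_48h: bool) -> list[LabResult]:
    horizon = min(los_h, p.vitals_horizon_days * 24.0)
    day_times = [6.0 + 24.0 * k for k in range(max(1, int(horizon // 24.0) + 1))
                 if 6.0 + 24.0 * k < los_h]
    if not day_times:
        day_times = [min(6.0, los_h * 0.5)]
    infected = cat is not SepsisCategory.NO_INFECTION

    out = []
    bases = {a: rng.normal(mu, sd) for a, (mu, sd, _) in _LAB_BASE.items()}
    for t in day_times:
        decay = (math.exp(-abs(t - onset_h) / _LAB_DECAY_H)
                 if infected and onset_h is not None else 0.0)
        when = adm_start + timedelta(hours=t)
        for a, (_, _, sd_day) in _LAB_BASE.items():
            v = bases[a] + rng.normal(0.0, sd_day)
            if infected:
                v += _LAB_EFFECTS[cat][a] * decay
            out.append(LabResult(timestamp=when, analyte=a,
                                 value=round(max(float(v), 1.0), 1)))
    # critical-care sepsis: arterial blood gases after onset
    if cc_48h and cat is SepsisCategory.SEPSIS and onset_h is not None:
        for t in (onset_h + 6.0, onset_h + 30.0):
            if 0 <= t < los_h and rng.random() < 0.6:
                when = adm_start + timedelta(hours=t)
                out.append(LabResult(when, Analyte.PAO2,
                                     round(max(float(rng.normal(10.0, 1.8)), 4.0), 1)))
                out.append(LabResult(when, Analyte.FIO2,
                                     float(rng.choice([0.28, 0.35, 0.40, 0.60]))))
    return out


def _make_episodes(rng: np.random.Generator, p: CohortParams,
                   adm_start: datetime, los_h: float, cc: bool,
                   onset_h: Optional[float]) -> list[WardEpisode]:
    end = adm_start + timedelta(hours=los_h)
    ward = f"W{int(rng.integers(1, p.n_wards + 1)):02d}"
    if not cc:
        return [WardEpisode(ward=ward, start=adm_start, end=end)]
    # critical-care episode anchored near onset when there is one
    anchor = onset_h if onset_h is not None else los_h * 0.3
    cc_start_h = float(np.clip(anchor + rng.uniform(-24.0, 24.0),
                               0.0, max(los_h - 12.0, 0.0)))
    cc_len = float(min(rng.uniform(24.0, 120.0), los_h - cc_start_h))
    cc_s = adm_start + timedelta(hours=cc_start_h)
    cc_e = cc_s + timedelta(hours=cc_len)
    eps = []
    if cc_start_h > 0:
        eps.append(WardEpisode(ward=ward, start=adm_start, end=cc_s))
    eps.append(WardEpisode(ward="ICU", start=cc_s, end=cc_e,
                           critical_care=True))
    if cc_e < end:
        eps.append(WardEpisode(ward=ward, start=cc_e, end=end))
    return eps


def generate_cohort(params: CohortParams) -> list[SyntheticAdmission]:
    """Generate a reproducible synthetic cohort (deterministic per seed)."""
    params.validate()
    p = params
    rng = _streams(p.seed)
    admissions: list[SyntheticAdmission] = []
    prev: Optional[SyntheticAdmission] = None

    for i in range(p.n_admissions):
        cat = _draw_category(rng["category"], p)
        short = rng["category"].random() < p.short_stay_rate
        maternity = rng["category"].random() < p.maternity_rate

        adm_start = p.start + timedelta(
            hours=float(rng["times"].uniform(0, p.study_days * 24.0)))
        patient_id = f"P{i:05d}"
        if prev is not None and rng["readmission"].random() < p.readmission_rate:
            patient_id = prev.patient_id
            adm_start = prev.discharged + timedelta(
                hours=float(rng["readmission"].uniform(49.0, 30 * 24.0)))
        los_h = _draw_los_hours(rng["times"], p, cat, short)

        infected = cat is not SepsisCategory.NO_INFECTION
        onset_h: Optional[float] = None
        if infected:
            if los_h < 30.0:
                onset_h = float(rng["times"].uniform(2.0, max(los_h - 4.0, 3.0)))
            else:
                onset_h = float(np.clip(abs(rng["times"].normal(8.0, 16.0)),
                                        0.0, min(los_h - 8.0, 72.0)))

        cc = rng["wards"].random() < p.critical_care_prob[cat.value]

        # mortality and severity (severity scales the vitals perturbation)
        dies = rng["mortality"].random() < p.mortality_30d[cat.value]
        severity = float(np.clip(
            rng["mortality"].normal(1.35 if dies else 0.95,
                                    0.15 if dies else 0.18), 0.5, 1.8))
        death: Optional[datetime] = None
        if dies:
            in_hosp = rng["mortality"].random() < 0.6 or los_h >= 719.0
            if in_hosp:
                at = float(rng["mortality"].uniform(
                    25.0, max(min(los_h, 719.0), 26.0)))
                death = adm_start + timedelta(hours=at)
                los_h = at
            else:
                death = adm_start + timedelta(
                    hours=float(rng["mortality"].uniform(los_h, 720.0)))

        discharged = adm_start + timedelta(hours=los_h)
        if onset_h is not None:
            onset_h = min(onset_h, max(los_h - 2.0, 1.0))

        vitals = _make_vitals(rng["vitals"], p, adm_start, los_h, cat,
                              onset_h, severity, cc)
        labs = _make_labs(rng["labs"], p, adm_start, los_h, cat, onset_h, cc)
        episodes = _make_episodes(rng["wards"], p, adm_start, los_h, cc, onset_h)

        # microbiology and antibiotics; onset = min(first culture, first abx)
        cultures: list[BloodCulture] = []
        antibiotics: list[Antibiotic] = []
        sampled = rng["micro"].random() < p.culture_sampling[cat.value]
        if infected and onset_h is not None:
            t0 = adm_start + timedelta(hours=onset_h)
            if sampled:
                res = CultureResult.NEGATIVE
                if (rng["micro"].random()
                        < p.culture_positive_given_sampled[cat.value]):
                    res = CultureResult.POSITIVE
                elif (rng["micro"].random()
                        < p.culture_contaminated_given_sampled):
                    res = CultureResult.CONTAMINATED
                cultures.append(BloodCulture(timestamp=t0, result=res))
                first_abx = t0 + timedelta(
                    hours=float(rng["micro"].uniform(0.0, 4.0)))
            else:
                first_abx = t0
            n_doses = int(rng["micro"].integers(4, 12))
            for k in range(n_doses):
                ts = first_abx + timedelta(hours=12.0 * k)
                if ts <= discharged:
                    antibiotics.append(Antibiotic(
                        timestamp=ts,
                        route="IV" if rng["micro"].random() < 0.8 else "oral"))
            if not antibiotics:
                antibiotics.append(Antibiotic(timestamp=first_abx, route="IV"))
        elif sampled:
            tc = adm_start + timedelta(
                hours=float(rng["micro"].uniform(2.0, max(los_h * 0.6, 3.0))))
            res = CultureResult.NEGATIVE
            if rng["micro"].random() < p.culture_positive_given_sampled[cat.value]:
                res = CultureResult.POSITIVE
            elif rng["micro"].random() < p.culture_contaminated_given_sampled:
                res = CultureResult.CONTAMINATED
            cultures.append(BloodCulture(timestamp=tc, result=res))

        # discharge coding
        codes: list[str] = []
        crng = rng["coding"]
        if crng.random() < p.sepsis_code_prob[cat.value]:
            codes.append(str(crng.choice(_SEPSIS_CODES)))
        if crng.random() < p.infection_code_prob[cat.value]:
            codes.extend(crng.choice(_INFECTION_CODES,
                                     size=int(crng.integers(1, 3)),
                                     replace=False).tolist())
        codes.extend(crng.choice(_NOISE_CODES, size=int(crng.integers(1, 4)),
                                 replace=False).tolist())

        admissions.append(SyntheticAdmission(
            admission_id=f"A{i:05d}", patient_id=patient_id,
            admitted=adm_start, discharged=discharged,
            age=int(np.clip(rng["category"].normal(
                72 if cat is SepsisCategory.SEPSIS else 66, 15), 16, 100)),
            female=bool(rng["category"].random() < 0.54),
            simd=int(rng["category"].integers(1, 6)),
            maternity=maternity, episodes=episodes, vitals=vitals, labs=labs,
            antibiotics=antibiotics, cultures=cultures, icd10_codes=codes,
            death_date=death, infection_source_documented=infected,
            true_category=cat,
            true_onset=(adm_start + timedelta(hours=onset_h))
            if onset_h is not None else None))
        prev = admissions[-1]
    return admissions


# ---------------------------------------------------------------------------
# Eligibility filters and 1:1 blood-culture matching
# ---------------------------------------------------------------------------

def apply_eligibility_filters(admissions: Sequence[Admission],
                              ) -> tuple[list[Admission], dict[str, int]]:
    """Remove maternity admissions and stays under 24 h.

    Returns the retained admissions and a per-reason exclusion count.
    """
    kept: list[Admission] = []
    log = {"maternity": 0, "los_lt_24h": 0}
    for adm in admissions:
        if adm.maternity:
            log["maternity"] += 1
        elif adm.los_hours < 24.0:
            log["los_lt_24h"] += 1
        else:
            kept.append(adm)
    return kept, log


@dataclass(slots=True)
class MatchedPair:
    case: Admission       # admission with a blood culture
    control: Admission    # matched admission without one
    critical_care: bool   # case was in critical care at culture time


def _episode_at(adm: Admission, when: datetime) -> Optional[WardEpisode]:
    for ep in adm.episodes:
        if ep.start <= when < ep.end:
            return ep
    return min(adm.episodes,
               key=lambda ep: min(abs((ep.start - when).total_seconds()),
                                  abs((ep.end - when).total_seconds())),
               default=None)


def match_culture_pairs(admissions: Sequence[Admission],
                        ) -> tuple[list[MatchedPair], list[Admission]]:
    """Greedy 1:1 matching of cultured to culture-free admissions.

    Cases are processed in chronological order of first culture.  A
    candidate control must occupy the same ward/clinical area within
    ±24 h of the culture (±96 h in critical care) and have a length of
    stay within ±24 h (±48 h in critical care).  Each control is used at
    most once; ties break on smallest LOS difference, then earliest
    admission.  Returns the matched pairs and the unmatched cases.
    """
    cases = sorted((a for a in admissions if a.cultures),
                   key=lambda a: min(c.timestamp for c in a.cultures))
    controls = [a for a in admissions if not a.cultures]
    by_ward: dict[str, list[Admission]] = {}
    for c in controls:
        for ep in c.episodes:
            by_ward.setdefault(ep.ward, []).append(c)

    used: set[str] = set()
    pairs: list[MatchedPair] = []
    unmatched: list[Admission] = []
    for case in cases:
        tc = min(c.timestamp for c in case.cultures)
        ep = _episode_at(case, tc)
        if ep is None:
            unmatched.append(case)
            continue
        cc = ep.critical_care
        t_win = timedelta(hours=96 if cc else 24)
        los_tol = 48.0 if cc else 24.0
        best: Optional[tuple[float, datetime, Admission]] = None
        for cand in by_ward.get(ep.ward, []):
            if cand.admission_id in used or cand.admission_id == case.admission_id:
                continue
            overlap = any(e.ward == ep.ward
                          and e.start <= tc + t_win and e.end >= tc - t_win
                          for e in cand.episodes)
            if not overlap:
                continue
            los_diff = abs(cand.los_hours - case.los_hours)
            if los_diff > los_tol:
                continue
            key = (los_diff, cand.admitted, cand)
            if best is None or key[:2] < (best[0], best[1]):
                best = key
        if best is None:
            unmatched.append(case)
        else:
            used.add(best[2].admission_id)
            pairs.append(MatchedPair(case=case, control=best[2],
                                     critical_care=cc))
    return pairs, unmatched


def sample_study_cohort(pairs: Sequence[MatchedPair], n_target: int,
                        seed: int) -> list[Admission]:
    """Assemble the analysis cohort from matched pairs.

    All critical-care pairs are always retained; ward pairs are sampled
    at random to bring the cohort to *n_target* admissions.  Pairs are
    kept or dropped as a unit.
    """
    cc_pairs = [p for p in pairs if p.critical_care]
    ward_pairs = [p for p in pairs if not p.critical_care]
    need = n_target - 2 * len(cc_pairs)
    if need < 0 or need > 2 * len(ward_pairs) or n_target % 2:
        raise ValueError(
            f"cannot reach n_target={n_target} from {len(pairs)} pairs "
            f"({len(cc_pairs)} critical care); n_target must be even")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(len(ward_pairs), size=need // 2, replace=False)) \
        if need else []
    out: list[Admission] = []
    for pr in cc_pairs + [ward_pairs[int(j)] for j in sorted(chosen)]:
        out.extend([pr.case, pr.control])
    return out
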