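"""CSV serialisation of cohorts.

A cohort is a directory of UTF-8 comma-separated files with mandatory
header rows, ISO-8601 timestamps and empty fields for missing values:
``admissions.csv``, ``episodes.csv``, ``vitals.csv``, ``labs.csv``,
``antibiotics.csv``, ``cultures.csv``, ``codes.csv`` and, for synthetic
cohorts, ``latent.csv`` with the generator's ground truth.

Column names can be remapped through a schema mapping (canonical name →
file column name), declared in the run-config file for externally
produced data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .model import (AVPU, Admission, Analyte, Antibiotic, BloodCulture,
                    CultureResult, LabResult, VitalsObservation, WardEpisode)
from .simulate import SyntheticAdmission

FILES = ("admissions", "episodes", "vitals", "labs", "antibiotics",
         "cultures", "codes")


def _opt(v):
    return None if pd.isna(v) else v


def write_cohort(admissions: Sequence[Admission], outdir) -> None:
    """Write a cohort to *outdir* (created if needed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = {name: [] for name in FILES + ("latent",)}
    for a in admissions:
        rows["admissions"].append({
            "admission_id": a.admission_id, "patient_id": a.patient_id,
            "admitted": a.admitted.isoformat(),
            "discharged": a.discharged.isoformat(),
            "age": a.age, "female": a.female, "simd": a.simd,
            "maternity": a.maternity,
            "death_date": a.death_date.isoformat() if a.death_date else None,
            "infection_source_documented": a.infection_source_documented})
        for ep in a.episodes:
            rows["episodes"].append({
                "admission_id": a.admission_id, "ward": ep.ward,
                "start": ep.start.isoformat(), "end": ep.end.isoformat(),
                "critical_care": ep.critical_care})
        for v in a.vitals:
            rows["vitals"].append({
                "admission_id": a.admission_id,
                "timestamp": v.timestamp.isoformat(),
                "respiratory_rate": v.respiratory_rate, "spo2": v.spo2,
                "supplemental_oxygen": v.supplemental_oxygen,
                "temperature": v.temperature, "systolic_bp": v.systolic_bp,
                "diastolic_bp": v.diastolic_bp, "heart_rate": v.heart_rate,
                "avpu": v.avpu.value if v.avpu else None, "gcs": v.gcs})
        for lab in a.labs:
            rows["labs"].append({
                "admission_id": a.admission_id,
                "timestamp": lab.timestamp.isoformat(),
                "analyte": lab.analyte.value, "value": lab.value})
        for ab in a.antibiotics:
            rows["antibiotics"].append({
                "admission_id": a.admission_id,
                "timestamp": ab.timestamp.isoformat(), "route": ab.route})
        for c in a.cultures:
            rows["cultures"].append({
                "admission_id": a.admission_id,
                "timestamp": c.timestamp.isoformat(),
                "result": c.result.value})
        for code in a.icd10_codes:
            rows["codes"].append({"admission_id": a.admission_id,
                                  "code": code})
        if isinstance(a, SyntheticAdmission):
            rows["latent"].append({
                "admission_id": a.admission_id,
                "true_category": a.true_category.value,
                "true_onset": a.true_onset.isoformat()
                if a.true_onset else None})
    for name in FILES:
        pd.DataFrame(rows[name]).to_csv(out / f"{name}.csv", index=False)
    if rows["latent"]:
        pd.DataFrame(rows["latent"]).to_csv(out / "latent.csv", index=False)


def read_cohort(indir, schema: Optional[dict] = None) -> list[Admission]:
    """Read a cohort directory back into Admission objects.

    *schema* optionally maps canonical column names to the names used in
    the files (applied to every file where the column occurs).
    """
    d = Path(indir)

    def load(name, parse=()):
        path = d / f"{name}.csv"
        if not path.exists():
            return pd.DataFrame()
        df = pd.read_csv(path)
        if schema:
            df = df.rename(columns={v: k for k, v in schema.items()})
        for col in parse:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        return df

    adm_df = load("admissions", parse=("admitted", "discharged", "death_date"))
    grouped = {}
    for name in ("episodes", "vitals", "labs", "antibiotics",
                 "cultures", "codes"):
        df = load(name, parse=("timestamp", "start", "end"))
        grouped[name] = ({k: g for k, g in df.groupby("admission_id")}
                         if not df.empty else {})
    latent_df = load("latent", parse=("true_onset",))
    latent = ({r.admission_id: r for r in latent_df.itertuples()}
              if not latent_df.empty else {})

    out: list[Admission] = []
    for r in adm_df.itertuples():
        aid = r.admission_id
        episodes = [WardEpisode(ward=e.ward, start=e.start.to_pydatetime(),
                                end=e.end.to_pydatetime(),
                                critical_care=bool(e.critical_care))
                    for e in grouped["episodes"].get(aid, pd.DataFrame()).itertuples()]
        vitals = [VitalsObservation(
            timestamp=v.timestamp.to_pydatetime(),
            respiratory_rate=_opt(v.respiratory_rate), spo2=_opt(v.spo2),
            supplemental_oxygen=None if pd.isna(v.supplemental_oxygen)
            else bool(v.supplemental_oxygen),
            temperature=_opt(v.temperature),
            systolic_bp=_opt(v.systolic_bp),
            diastolic_bp=_opt(v.diastolic_bp),
            heart_rate=_opt(v.heart_rate),
            avpu=AVPU(v.avpu) if isinstance(v.avpu, str) else None,
            gcs=None if pd.isna(v.gcs) else int(v.gcs))
            for v in grouped["vitals"].get(aid, pd.DataFrame()).itertuples()]
        labs = [LabResult(timestamp=l.timestamp.to_pydatetime(),
                          analyte=Analyte(l.analyte), value=float(l.value))
                for l in grouped["labs"].get(aid, pd.DataFrame()).itertuples()]
        abx = [Antibiotic(timestamp=x.timestamp.to_pydatetime(), route=x.route)
               for x in grouped["antibiotics"].get(aid, pd.DataFrame()).itertuples()]
        cultures = [BloodCulture(timestamp=c.timestamp.to_pydatetime(),
                                 result=CultureResult(c.result))
                    for c in grouped["cultures"].get(aid, pd.DataFrame()).itertuples()]
        codes = [c.code for c in
                 grouped["codes"].get(aid, pd.DataFrame()).itertuples()]
        kwargs = dict(
            admission_id=aid, patient_id=str(r.patient_id),
            admitted=r.admitted.to_pydatetime(),
            discharged=r.discharged.to_pydatetime(),
            age=None if pd.isna(r.age) else int(r.age),
            female=None if pd.isna(r.female) else bool(r.female),
            simd=None if pd.isna(r.simd) else int(r.simd),
            maternity=bool(r.maternity), episodes=episodes, vitals=vitals,
            labs=labs, antibiotics=abx, cultures=cultures, icd10_codes=codes,
            death_date=None if pd.isna(r.death_date)
            else r.death_date.to_pydatetime(),
            infection_source_documented=bool(r.infection_source_documented))
        if aid in latent:
            from .model import SepsisCategory
            lr = latent[aid]
            out.append(SyntheticAdmission(
                **kwargs,
                true_category=SepsisCategory(lr.true_category),
                true_onset=None if pd.isna(lr.true_onset)
                else lr.true_onset.to_pydatetime()))
        else:
            out.append(Admission(**kwargs))
    return out
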