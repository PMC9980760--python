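"""End-to-end orchestration: label a cohort and build the report grids.

The report bundle contains a cohort summary by category, the
severity-score performance grid for the selected mortality endpoint,
the administrative-data evaluation grid against the selected reference,
and the per-score ROC data.  Every table carries the run seed and a
content hash of the configuration for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .labels import classify_sepsis
from .model import Admission
from .perf import auroc_with_ci, delong_test, roc_curve, round_half_up
from .simulate import CohortParams, SyntheticAdmission, generate_cohort
from .surveillance import (INDICATOR_LABELS, INDICATOR_ORDER, CodeLists,
                           build_indicators, evaluate_indicators)

log = logging.getLogger(__name__)

ENDPOINTS = ("mortality_30d_from_onset", "mortality_30d_from_admission",
             "in_hospital_death")
REFERENCES = ("sepsis3", "infection_news7")

#: clinical cut-offs applied to each instrument in the score grid
SCORE_CUTOFFS = (("sofa", 2), ("news", 5), ("news", 7), ("sirs", 2),
                 ("qsofa", 2))


@dataclass
class RunConfig:
    """Pipeline configuration (defaults reproduce the standard analysis)."""

    seed: int = 0
    simulate_n: Optional[int] = None          # generate instead of reading
    cohort_dir: Optional[str] = None
    endpoint: str = "mortality_30d_from_onset"
    reference: str = "sepsis3"
    ci_method: str = "clopper-pearson"
    baseline_mode: str = "min_pre"
    news7_threshold: int = 7
    code_list_sepsis: Optional[str] = None
    code_list_infection: Optional[str] = None
    schema: Optional[dict] = None

    def validate(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if self.reference not in REFERENCES:
            raise ValueError(f"reference must be one of {REFERENCES}")

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def label_cohort(admissions: Sequence[Admission],
                 baseline_mode: str = "min_pre") -> pd.DataFrame:
    """One row per admission: category, SOFA, analysis scores, endpoints."""
    rows = []
    for adm in admissions:
        lab = classify_sepsis(adm, baseline_mode=baseline_mode)
        s = lab.analysis_scores
        rows.append({
            "admission_id": adm.admission_id,
            "category": lab.category.value,
            "max_sofa": lab.max_sofa,
            "delta_sofa": lab.delta_sofa,
            "critical_care_48h": lab.critical_care_48h,
            "news": s.news, "qsofa": s.qsofa, "sirs": s.sirs,
            "sofa": lab.delta_sofa if lab.critical_care_48h else lab.max_sofa,
            "mortality_30d_from_onset": lab.mortality_30d_from_onset,
            "mortality_30d_from_admission": lab.mortality_30d_from_admission,
            "in_hospital_death": lab.in_hospital_death,
            "true_category": adm.true_category.value
            if isinstance(adm, SyntheticAdmission) else None,
        })
    return pd.DataFrame(rows)


def cohort_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Descriptive counts by category (no hypothesis tests)."""
    rows = []
    for cat in ("sepsis", "infection_no_sepsis", "no_infection"):
        sub = labels[labels.category == cat]
        rows.append({
            "category": cat, "n": len(sub),
            "mortality_30d_from_admission": int(sub.mortality_30d_from_admission.sum()),
            "in_hospital_death": int(sub.in_hospital_death.sum()),
            "median_news": float(sub.news.median()) if len(sub) else np.nan,
        })
    rows.append({"category": "all", "n": len(labels),
                 "mortality_30d_from_admission":
                     int(labels.mortality_30d_from_admission.sum()),
                 "in_hospital_death": int(labels.in_hospital_death.sum()),
                 "median_news": float(labels.news.median())
                 if len(labels) else np.nan})
    return pd.DataFrame(rows)


def score_performance_grid(labels: pd.DataFrame,
                           endpoint: str = "mortality_30d_from_onset",
                           ci_method: str = "clopper-pearson") -> pd.DataFrame:
    """Severity-score accuracy for the mortality endpoint, infected only.

    The SOFA row uses the Sepsis-3 decision itself (max SOFA ≥2 on the
    ward, ΔSOFA ≥2 in critical care); the other rows threshold the
    highest-acuity scores at their clinical cut-offs.
    """
    from .perf import accuracy_stats, two_by_two

    if labels.empty:
        raise ValueError("empty cohort")
    inf = labels[labels.category != "no_infection"]
    if inf.empty:
        raise ValueError("no infected admissions to evaluate")
    truth = inf[endpoint].to_numpy(dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError(f"degenerate endpoint {endpoint}: one class only")
    rows = []
    for score, cut in SCORE_CUTOFFS:
        if score == "sofa":
            pred = (inf.category == "sepsis").to_numpy()
        else:
            pred = (inf[score] >= cut).to_numpy()
        t = two_by_two(pred, truth)
        perf = accuracy_stats(t, ci_method)
        auc = auroc_with_ci(inf[score].to_numpy(float), truth)
        rows.append({
            "instrument": f"{score.upper()} >={cut}",
            "n_above": int(pred.sum()),
            "deaths_above": t.tp, "deaths_below": t.fn,
            "sensitivity": perf.sensitivity.pct(),
            "specificity": perf.specificity.pct(),
            "ppv": perf.ppv.pct() if perf.ppv else "undefined",
            "npv": perf.npv.pct() if perf.npv else "undefined",
            "auroc_all_values": round_half_up(auc.point, 2),
            "auroc_lo": round_half_up(auc.lo, 2),
            "auroc_hi": round_half_up(auc.hi, 2),
        })
    return pd.DataFrame(rows)


def delong_comparisons(labels: pd.DataFrame,
                       endpoint: str = "mortality_30d_from_onset",
                       against: str = "sofa") -> pd.DataFrame:
    """DeLong's paired test of each score's AUROC against one comparator."""
    inf = labels[labels.category != "no_infection"]
    truth = inf[endpoint].to_numpy(dtype=bool)
    base = inf[against].to_numpy(float)
    rows = []
    for score in ("news", "qsofa", "sirs"):
        res = delong_test(base, inf[score].to_numpy(float), truth)
        rows.append({"comparison": f"{against} vs {score}",
                     "auroc_a": round_half_up(res.auroc_a.point, 2),
                     "auroc_b": round_half_up(res.auroc_b.point, 2),
                     "z": round_half_up(res.z, 3),
                     "p_two_sided": round_half_up(res.p_two_sided, 3)})
    return pd.DataFrame(rows)


def admin_reference(labels: pd.DataFrame, reference: str = "sepsis3",
                    news7: int = 7) -> np.ndarray:
    """Per-admission reference truth for the administrative evaluation."""
    if reference == "sepsis3":
        return (labels.category == "sepsis").to_numpy()
    return ((labels.category != "no_infection")
            & (labels.news >= news7)).to_numpy()


def admin_performance_grid(admissions: Sequence[Admission],
                           labels: pd.DataFrame,
                           reference: str = "sepsis3",
                           lists: Optional[CodeLists] = None,
                           ci_method: str = "clopper-pearson",
                           news7: int = 7) -> pd.DataFrame:
    """Administrative-indicator evaluation grid in reporting order."""
    lists = lists or CodeLists.default()
    inds = [build_indicators(a.icd10_codes, a.cultures, lists)
            for a in admissions]
    ref = admin_reference(labels, reference, news7)
    grid = evaluate_indicators(inds, ref, ci_method=ci_method)
    rows = []
    for name in INDICATOR_ORDER:
        perf = grid[name]
        t = perf.table
        rows.append({
            "indicator": INDICATOR_LABELS[name],
            "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
            "sensitivity": perf.sensitivity.pct(),
            "specificity": perf.specificity.pct(),
            "ppv": perf.ppv.pct() if perf.ppv else "undefined",
            "npv": perf.npv.pct() if perf.npv else "undefined",
            "auroc": round_half_up(perf.auroc.point, 2) if perf.auroc else None,
        })
    return pd.DataFrame(rows)


def roc_data(labels: pd.DataFrame,
             endpoint: str = "mortality_30d_from_onset") -> pd.DataFrame:
    """ROC staircases for all four scores (infected admissions)."""
    inf = labels[labels.category != "no_infection"]
    truth = inf[endpoint].to_numpy(dtype=bool)
    rows = []
    for score in ("sofa", "news", "qsofa", "sirs"):
        for fpr, tpr, thr in roc_curve(inf[score].to_numpy(float), truth):
            rows.append({"score": score, "fpr": fpr, "tpr": tpr,
                         "threshold": thr})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute (simulate →) label → evaluate and return the report bundle."""
    config.validate()
    if config.simulate_n is not None:
        log.info("simulating cohort of %d admissions", config.simulate_n)
        admissions = generate_cohort(CohortParams(
            n_admissions=config.simulate_n, seed=config.seed))
    elif config.cohort_dir:
        from .io import read_cohort
        admissions = read_cohort(config.cohort_dir, schema=config.schema)
    else:
        raise ValueError("config must set simulate_n or cohort_dir")
    log.info("labelling %d admissions", len(admissions))
    labels = label_cohort(admissions, baseline_mode=config.baseline_mode)

    lists = CodeLists.default()
    if config.code_list_sepsis and config.code_list_infection:
        lists = CodeLists.from_files(config.code_list_sepsis,
                                     config.code_list_infection)
    bundle = {
        "meta": {"seed": config.seed, "config_hash": config.content_hash(),
                 "n_admissions": len(admissions),
                 "endpoint": config.endpoint, "reference": config.reference},
        "labels": labels,
        "cohort_summary": cohort_summary(labels),
        "score_performance": score_performance_grid(
            labels, config.endpoint, config.ci_method),
        "delong": delong_comparisons(labels, config.endpoint),
        "admin_performance": admin_performance_grid(
            admissions, labels, config.reference, lists, config.ci_method,
            config.news7_threshold),
        "roc": roc_data(labels, config.endpoint),
    }
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    """Write every table of a report bundle to *outdir* plus metadata."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if name == "meta":
            (out / "meta.json").write_text(json.dumps(obj, indent=2))
        else:
            obj.to_csv(out / f"{name}.csv", index=False)
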