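"""Calibration experiments on large synthetic cohorts.

These run the whole pipeline — generate, score, label, build
administrative indicators — and compare the measured conditional rates
with the generator's own parameters.  They are the package's evidence
that the scoring and labelling machinery recovers a known ground truth.
"""

from __future__ import annotations

import math

import numpy as np

from .pipeline import label_cohort
from .perf import empirical_auroc
from .simulate import CohortParams, generate_cohort
from .surveillance import CodeLists


def parameter_recovery(n: int = 20_000, seed: int = 7,
                       params: CohortParams | None = None) -> dict:
    """End-to-end parameter recovery on an *n*-admission synthetic cohort.

    Returns a mapping of measured quantities, each a dict with
    ``value``, the generator's ``target`` and the Monte-Carlo standard
    error of the measurement; plus the mortality AUROC of each severity
    score among infected admissions.
    """
    p = params or CohortParams(n_admissions=n, seed=seed)
    adms = generate_cohort(p)
    labels = label_cohort(adms)
    lists = CodeLists.default()

    true_cat = np.array([a.true_category.value for a in adms])
    infected = true_cat != "no_infection"
    labelled_sepsis = (labels.category == "sepsis").to_numpy()

    def rate(mask, value_mask, target):
        k, m = int((mask & value_mask).sum()), int(mask.sum())
        v = k / m
        return {"value": v, "target": target,
                "se": math.sqrt(max(v * (1 - v), 1e-12) / m), "n": m}

    out: dict[str, dict] = {
        "sepsis_given_infection_labelled": rate(
            infected, labelled_sepsis, p.sepsis_given_infection),
        "sepsis_given_infection_latent": rate(
            infected, true_cat == "sepsis", p.sepsis_given_infection),
    }
    has_sep_code = np.array([any(lists.is_sepsis_code(c)
                                 for c in a.icd10_codes) for a in adms])
    has_culture = np.array([len(a.cultures) > 0 for a in adms])
    died_30d_adm = labels.mortality_30d_from_admission.to_numpy()
    out["sepsis_code_sensitivity"] = rate(
        true_cat == "sepsis", has_sep_code, p.sepsis_code_prob["sepsis"])
    for cat in ("sepsis", "infection_no_sepsis", "no_infection"):
        out[f"culture_sampling_{cat}"] = rate(
            true_cat == cat, has_culture, p.culture_sampling[cat])
        out[f"mortality_30d_{cat}"] = rate(
            true_cat == cat, died_30d_adm, p.mortality_30d[cat])

    inf = labels[infected]
    truth = inf.mortality_30d_from_onset.to_numpy(bool)
    for score in ("news", "sofa", "qsofa", "sirs"):
        out[f"auroc_{score}_mortality"] = {
            "value": empirical_auroc(inf[score].to_numpy(float), truth),
            "target": None, "se": None, "n": int(infected.sum())}
    return out
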