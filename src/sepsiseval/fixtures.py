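"""Reference contingency tables for the ``reproduce-tables`` command.

These are the benchmark counts the evaluation statistics are checked
against: a severity-score grid (each row: deaths above / below the
clinical cut-off among infected patients) and an administrative-data
indicator grid (each row a full 2×2 against the sepsis reference).
Recomputing the published statistics from these counts exercises every
display path of :mod:`sepsiseval.perf`.
"""

from __future__ import annotations

from .perf import (DiagnosticPerformance, TwoByTwo, accuracy_stats,
                   binary_auroc)

#: Severity-score rows: (deaths at/above cut-off, n at/above,
#: deaths below, n below), among patients with infection (n = 630).
SCORE_PERFORMANCE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "SOFA >=2": (65, 347, 13, 283),
    "NEWS >=5": (66, 336, 12, 294),
    "NEWS >=7": (53, 200, 25, 430),
    "SIRS >=2": (70, 405, 8, 225),
    "qSOFA >=2": (33, 88, 45, 542),
}

#: Administrative-indicator rows: (tp, fp, fn, tn) against the
#: Sepsis-3 reference (347 sepsis / 611 non-sepsis admissions).
ADMIN_INDICATOR_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "infection_code": (226, 198, 121, 413),
    "sepsis_code": (27, 15, 320, 596),
    "infection_or_sepsis_code": (243, 210, 104, 401),
    "blood_culture": (229, 250, 118, 361),
    "positive_blood_culture": (26, 16, 321, 595),
    "code_or_culture": (303, 313, 44, 298),
    "code_and_culture": (169, 147, 178, 464),
}


def score_two_by_two(row: tuple[int, int, int, int]) -> TwoByTwo:
    """2×2 from a (deaths above, n above, deaths below, n below) row.

    Predicted positive = at/above the cut-off; truth = death.
    """
    d_above, n_above, d_below, n_below = row
    return TwoByTwo(tp=d_above, fp=n_above - d_above,
                    fn=d_below, tn=n_below - d_below)


def score_grid(ci_method: str = "clopper-pearson",
               ) -> dict[str, DiagnosticPerformance]:
    """Accuracy statistics for every severity-score row."""
    return {name: accuracy_stats(score_two_by_two(row), ci_method)
            for name, row in SCORE_PERFORMANCE_COUNTS.items()}


def admin_grid(ci_method: str = "clopper-pearson",
               ) -> dict[str, DiagnosticPerformance]:
    """Accuracy statistics plus binary AUROC for every indicator row."""
    out: dict[str, DiagnosticPerformance] = {}
    for name, (tp, fp, fn, tn) in ADMIN_INDICATOR_COUNTS.items():
        t = TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)
        perf = accuracy_stats(t, ci_method)
        perf.auroc = binary_auroc(t)
        out[name] = perf
    return out
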