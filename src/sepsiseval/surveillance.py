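"""Administrative-data sepsis indicators and their evaluation.

Builds per-admission booleans from ICD-10 discharge codes and
blood-culture records — infection code, explicit sepsis code
(A40*/A41*/R57.2), any code, culture sampled, culture positive, and the
OR/AND combinations — then scores each indicator against a reference
sepsis definition (the Sepsis-3 label, or infection with NEWS ≥7) using
the :mod:`sepsiseval.perf` statistics.

Code lists are plain text (one code or prefix per line, ``#`` comments);
matching is by canonical prefix, so ``A41`` covers ``A41.9``.  Code
position (primary vs secondary diagnosis) is ignored by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import BloodCulture, CultureResult, InvalidInputError
from .perf import DiagnosticPerformance, accuracy_stats, binary_auroc, two_by_two

_CODE_RE = re.compile(r"^[A-Z][0-9]{1,2}(\.[0-9A-Z]{1,4})?$")

#: Evaluation-grid rows, in reporting order.
INDICATOR_ORDER = (
    "infection_code",
    "sepsis_code",
    "infection_or_sepsis_code",
    "blood_culture",
    "positive_blood_culture",
    "code_or_culture",
    "code_and_culture",
)

INDICATOR_LABELS = {
    "infection_code": "Infection code",
    "sepsis_code": "Sepsis code",
    "infection_or_sepsis_code": "Infection or sepsis code",
    "blood_culture": "Blood culture",
    "positive_blood_culture": "Positive blood culture",
    "code_or_culture": "Infection or sepsis code or blood culture",
    "code_and_culture": "Infection or sepsis code plus blood culture",
}


def normalise_icd10(code: str) -> str:
    """Canonicalise an ICD-10 code: uppercase, dotted form (A419 → A41.9)."""
    c = code.strip().upper().replace(" ", "")
    if "." not in c and len(c) > 3:
        c = c[:3] + "." + c[3:]
    if not c or not _CODE_RE.match(c):
        raise InvalidInputError(f"malformed ICD-10 code {code!r}")
    return c


def _matches(code: str, prefixes: frozenset[str]) -> bool:
    """Prefix match on the undotted form, so A41 covers A41.9."""
    plain = code.replace(".", "")
    return any(plain.startswith(p.replace(".", "")) for p in prefixes)


def _load_list(path_or_lines: Iterable[str]) -> frozenset[str]:
    out = set()
    for line in path_or_lines:
        line = line.split("#", 1)[0].strip()
        if line:
            out.add(normalise_icd10(line))
    return frozenset(out)


@dataclass(frozen=True)
class CodeLists:
    """Sepsis and infection ICD-10 code/prefix sets (disjoint)."""

    sepsis_codes: frozenset[str]
    infection_codes: frozenset[str]

    def __post_init__(self) -> None:
        # any infection entry falling under a sepsis prefix is dropped
        cleaned = frozenset(c for c in self.infection_codes
                            if not _matches(c, self.sepsis_codes))
        object.__setattr__(self, "infection_codes", cleaned)

    @classmethod
    def default(cls) -> "CodeLists":
        """The packaged lists (the infection list is a reconstruction)."""
        pkg = resources.files("sepsiseval") / "data"
        return cls.from_files(pkg / "sepsis_codes.txt",
                              pkg / "infection_codes.txt")

    @classmethod
    def from_files(cls, sepsis_path, infection_path) -> "CodeLists":
        sep = _load_list(Path(str(sepsis_path)).read_text().splitlines())
        inf = _load_list(Path(str(infection_path)).read_text().splitlines())
        return cls(sepsis_codes=sep, infection_codes=inf)

    def is_sepsis_code(self, code: str) -> bool:
        return _matches(normalise_icd10(code), self.sepsis_codes)

    def is_infection_code(self, code: str) -> bool:
        c = normalise_icd10(code)
        return _matches(c, self.infection_codes) and not _matches(c, self.sepsis_codes)


@dataclass(slots=True)
class AdminIndicators:
    """Per-admission administrative-data booleans."""

    has_infection_code: bool = False
    has_sepsis_code: bool = False
    has_any_code: bool = False
    has_blood_culture: bool = False
    has_positive_culture: bool = False
    code_or_culture: bool = False
    code_and_culture: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {
            "infection_code": self.has_infection_code,
            "sepsis_code": self.has_sepsis_code,
            "infection_or_sepsis_code": self.has_any_code,
            "blood_culture": self.has_blood_culture,
            "positive_blood_culture": self.has_positive_culture,
            "code_or_culture": self.code_or_culture,
            "code_and_culture": self.code_and_culture,
        }


def build_indicators(admission_codes: Sequence[str],
                     cultures: Sequence[BloodCulture],
                     lists: Optional[CodeLists] = None) -> AdminIndicators:
    """Derive the seven indicator booleans for one admission.

    Contaminated cultures count as sampled but never as positive.
    """
    lists = lists or CodeLists.default()
    inf = any(lists.is_infection_code(c) for c in admission_codes)
    sep = any(lists.is_sepsis_code(c) for c in admission_codes)
    sampled = len(cultures) > 0
    positive = any(c.result is CultureResult.POSITIVE for c in cultures)
    any_code = inf or sep
    return AdminIndicators(
        has_infection_code=inf, has_sepsis_code=sep, has_any_code=any_code,
        has_blood_culture=sampled, has_positive_culture=positive,
        code_or_culture=any_code or sampled,
        code_and_culture=any_code and sampled)


def evaluate_indicators(indicators: Sequence[AdminIndicators],
                        reference: Sequence[bool],
                        ci_method: str = "clopper-pearson",
                        ) -> dict[str, DiagnosticPerformance]:
    """Evaluation grid: one DiagnosticPerformance row per indicator.

    *reference* is the per-admission truth (Sepsis-3 sepsis, or the
    configured alternative).  Rows are returned in reporting order.
    """
    if len(indicators) == 0:
        raise ValueError("empty cohort")
    if len(indicators) != len(reference):
        raise ValueError("indicators and reference must have equal length")
    grid: dict[str, DiagnosticPerformance] = {}
    for name in INDICATOR_ORDER:
        pred = [ind.as_dict()[name] for ind in indicators]
        t = two_by_two(pred, reference)
        perf = accuracy_stats(t, ci_method=ci_method)
        if t.positives > 0 and t.negatives > 0:
            perf.auroc = binary_auroc(t)
        grid[name] = perf
    return grid
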