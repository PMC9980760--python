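from datetime import datetime, timedelta

import pytest

from sepsiseval.model import (Admission, Analyte, Antibiotic, LabResult,
                              VitalsObservation, WardEpisode)

T0 = datetime(2015, 11, 2, 10, 0)


def hours(h: float) -> timedelta:
    return timedelta(hours=h)


def obs(dt_h: float = 0.0, **kw) -> VitalsObservation:
    return VitalsObservation(timestamp=T0 + hours(dt_h), **kw)


def lab(dt_h: float, analyte: str, value: float) -> LabResult:
    return LabResult(timestamp=T0 + hours(dt_h), analyte=Analyte(analyte),
                     value=value)


@pytest.fixture
def ward_admission():
    """An infected ward admission with onset at T0 (first antibiotic)."""
    adm = Admission(
        admission_id="A1", admitted=T0 - hours(6), discharged=T0 + hours(96),
        episodes=[WardEpisode(ward="W01", start=T0 - hours(6),
                              end=T0 + hours(96))],
        antibiotics=[Antibiotic(timestamp=T0)],
        infection_source_documented=True)
    return adm


@pytest.fixture
def small_cohort():
    """A tiny deterministic synthetic cohort for pipeline tests."""
    from sepsiseval.simulate import CohortParams, generate_cohort
    return generate_cohort(CohortParams(n_admissions=400, seed=11))
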