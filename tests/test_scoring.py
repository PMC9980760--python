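"""Band-boundary, range and monotonicity tests for the four score engines."""

import pytest
from hypothesis import given, settings, strategies as st

from sepsiseval.model import AVPU, InvalidInputError, VitalsObservation
from sepsiseval.scoring import (avpu_to_cns_points, news_score, qsofa_score,
                                sirs_score, sofa_coagulation_points,
                                sofa_cardiovascular_points, sofa_liver_points,
                                sofa_renal_points, sofa_respiration_points,
                                sofa_score)

from conftest import obs


# --- NEWS ------------------------------------------------------------------

@pytest.mark.parametrize("field,value,expected", [
    # respiratory rate: <=8 -> 3, 9-11 -> 1, 12-20 -> 0, 21-24 -> 2, >=25 -> 3
    ("respiratory_rate", 8, 3), ("respiratory_rate", 9, 1),
    ("respiratory_rate", 11, 1), ("respiratory_rate", 12, 0),
    ("respiratory_rate", 20, 0), ("respiratory_rate", 21, 2),
    ("respiratory_rate", 24, 2), ("respiratory_rate", 25, 3),
    # SpO2: <=91 -> 3, 92-93 -> 2, 94-95 -> 1, >=96 -> 0
    ("spo2", 91, 3), ("spo2", 92, 2), ("spo2", 93, 2), ("spo2", 94, 1),
    ("spo2", 95, 1), ("spo2", 96, 0),
    # temperature: <=35.0 -> 3, 35.1-36.0 -> 1, 36.1-38.0 -> 0,
    # 38.1-39.0 -> 1, >=39.1 -> 2
    ("temperature", 35.0, 3), ("temperature", 35.1, 1),
    ("temperature", 36.0, 1), ("temperature", 36.1, 0),
    ("temperature", 38.0, 0), ("temperature", 38.1, 1),
    ("temperature", 39.0, 1), ("temperature", 39.1, 2),
    # systolic BP: <=90 -> 3, 91-100 -> 2, 101-110 -> 1, 111-219 -> 0, >=220 -> 3
    ("systolic_bp", 90, 3), ("systolic_bp", 91, 2), ("systolic_bp", 100, 2),
    ("systolic_bp", 101, 1), ("systolic_bp", 110, 1), ("systolic_bp", 111, 0),
    ("systolic_bp", 219, 0), ("systolic_bp", 220, 3),
    # heart rate: <=40 -> 3, 41-50 -> 1, 51-90 -> 0, 91-110 -> 1,
    # 111-130 -> 2, >=131 -> 3
    ("heart_rate", 40, 3), ("heart_rate", 41, 1), ("heart_rate", 50, 1),
    ("heart_rate", 51, 0), ("heart_rate", 90, 0), ("heart_rate", 91, 1),
    ("heart_rate", 110, 1), ("heart_rate", 111, 2), ("heart_rate", 130, 2),
    ("heart_rate", 131, 3),
])
def test_news_band_boundaries(field, value, expected):
    total, breakdown = news_score(obs(**{field: value}))
    assert total == expected
    assert breakdown.get(field, 0) == expected


@pytest.mark.parametrize("avpu,pts", [(AVPU.A, 0), (AVPU.V, 3), (AVPU.P, 3),
                                      (AVPU.U, 3)])
def test_news_avpu(avpu, pts):
    assert news_score(obs(avpu=avpu))[0] == pts


def test_news_supplemental_oxygen_scores_two():
    assert news_score(obs(supplemental_oxygen=True))[0] == 2
    assert news_score(obs(supplemental_oxygen=False))[0] == 0


def test_news_normal_observation_scores_zero():
    v = obs(respiratory_rate=18, spo2=97, supplemental_oxygen=False,
            temperature=36.8, systolic_bp=120, heart_rate=75, avpu=AVPU.A)
    assert news_score(v)[0] == 0


def test_news_maximal_observation_scores_twenty():
    v = obs(respiratory_rate=25, spo2=90, supplemental_oxygen=True,
            temperature=35.0, systolic_bp=88, heart_rate=135, avpu=AVPU.P)
    assert news_score(v)[0] == 20


def test_news_partial_observation():
    # RR 21-24 and SBP 91-100 each score 2 with everything else normal
    v = obs(respiratory_rate=22, systolic_bp=95, spo2=97, temperature=37.0,
            heart_rate=70, supplemental_oxygen=False, avpu=AVPU.A)
    assert news_score(v)[0] == 4


def test_news_invalid_input():
    with pytest.raises(InvalidInputError):
        news_score(obs(spo2=105))
    with pytest.raises(InvalidInputError):
        news_score(obs(respiratory_rate=-2))


# --- SIRS ------------------------------------------------------------------

@pytest.mark.parametrize("kw,wcc,expected", [
    (dict(heart_rate=95, respiratory_rate=22, temperature=38.5), 13, 4),
    (dict(heart_rate=80, respiratory_rate=16, temperature=37.0), 8, 0),
    # strict inequalities at each boundary
    (dict(heart_rate=90), None, 0), (dict(heart_rate=91), None, 1),
    (dict(respiratory_rate=20), None, 0), (dict(respiratory_rate=21), None, 1),
    (dict(temperature=36.0), None, 0), (dict(temperature=35.8), None, 1),
    (dict(temperature=38.0), None, 0), (dict(temperature=38.1), None, 1),
    (dict(), 4.0, 0), (dict(), 3.9, 1), (dict(), 12.0, 0), (dict(), 12.1, 1),
])
def test_sirs_criteria(kw, wcc, expected):
    assert sirs_score(obs(**kw), wcc) == expected


# --- qSOFA -----------------------------------------------------------------

@pytest.mark.parametrize("kw,expected", [
    (dict(respiratory_rate=22, systolic_bp=100, avpu=AVPU.A), 2),  # inclusive
    (dict(respiratory_rate=21, systolic_bp=101, avpu=AVPU.A), 0),
    (dict(respiratory_rate=16, systolic_bp=120, gcs=15), 0),
    (dict(respiratory_rate=30, systolic_bp=80, avpu=AVPU.V), 3),
    (dict(gcs=13), 1), (dict(gcs=14), 0),
    (dict(gcs=14, avpu=AVPU.U), 0),   # recorded GCS takes precedence
    (dict(avpu=AVPU.V), 1),
])
def test_qsofa_criteria(kw, expected):
    assert qsofa_score(obs(**kw)) == expected


# --- SOFA components -------------------------------------------------------

@pytest.mark.parametrize("spo2,expected", [
    (96, 0), (95, 0), (94.9, 1), (94, 1), (91, 1), (90.9, 2), (90, 2), (60, 2),
])
def test_sofa_respiration_spo2_substitution(spo2, expected):
    assert sofa_respiration_points(spo2=spo2) == expected


@pytest.mark.parametrize("ratio_mmhg,support,expected", [
    (450, False, 0), (399, False, 1), (299, False, 2),
    (199, True, 3), (199, False, 2), (99, True, 4), (99, False, 2),
])
def test_sofa_respiration_pf_ratio(ratio_mmhg, support, expected):
    pao2_kpa = ratio_mmhg * 0.5 / 7.50062  # FiO2 0.5
    assert sofa_respiration_points(pao2=pao2_kpa, fio2=0.5,
                                   supplemental_oxygen=support) == expected


def test_blood_gas_takes_precedence_over_spo2():
    # ratio 450 scores 0 even though SpO2 alone would score 2
    pao2 = 450 * 0.3 / 7.50062
    assert sofa_respiration_points(pao2=pao2, fio2=0.3, spo2=88) == 0


def test_sofa_respiration_invalid_fio2():
    with pytest.raises(InvalidInputError):
        sofa_respiration_points(pao2=10, fio2=0.1)


@pytest.mark.parametrize("gcs,avpu,expected", [
    (15, None, 0), (14, None, 1), (13, None, 1), (12, None, 2), (10, None, 2),
    (9, None, 3), (6, None, 3), (5, None, 4), (3, None, 4),
    (None, AVPU.A, 0), (None, AVPU.V, 1), (None, AVPU.P, 3), (None, AVPU.U, 4),
    (14, AVPU.U, 1),   # recorded GCS wins over AVPU
    (None, None, 0),
])
def test_cns_points(gcs, avpu, expected):
    assert avpu_to_cns_points(avpu=avpu, gcs=gcs) == expected


@pytest.mark.parametrize("plt,expected", [
    (200, 0), (150, 0), (149, 1), (100, 1), (99, 2), (50, 2), (49, 3),
    (20, 3), (19, 4),
])
def test_coagulation_bands(plt, expected):
    assert sofa_coagulation_points(plt) == expected


@pytest.mark.parametrize("bili,expected", [
    (10, 0), (19, 0), (20, 1), (32, 1), (33, 2), (101, 2), (102, 3),
    (204, 3), (205, 4),
])
def test_liver_bands(bili, expected):
    assert sofa_liver_points(bili) == expected


@pytest.mark.parametrize("creat,expected", [
    (90, 0), (109, 0), (110, 1), (170, 1), (171, 2), (299, 2), (300, 3),
    (440, 3), (441, 4),
])
def test_renal_bands(creat, expected):
    assert sofa_renal_points(creat) == expected


def test_renal_urine_output_alternative():
    assert sofa_renal_points(90, urine_output_ml=450) == 3
    assert sofa_renal_points(90, urine_output_ml=150) == 4
    assert sofa_renal_points(500, urine_output_ml=450) == 4  # worse wins


def test_cardiovascular_map_and_vasopressors():
    assert sofa_cardiovascular_points(75) == 0
    assert sofa_cardiovascular_points(69) == 1
    assert sofa_cardiovascular_points(None) == 0  # missing-as-normal
    assert sofa_cardiovascular_points(65, "dobutamine") == 2
    assert sofa_cardiovascular_points(65, "dopamine", 4) == 2
    assert sofa_cardiovascular_points(65, "dopamine", 6) == 3
    assert sofa_cardiovascular_points(65, "dopamine", 16) == 4
    assert sofa_cardiovascular_points(65, "noradrenaline", 0.05) == 3
    assert sofa_cardiovascular_points(65, "noradrenaline", 0.2) == 4


def test_sofa_total_composition():
    v = obs(systolic_bp=80, diastolic_bp=57, spo2=96, avpu=AVPU.A)
    ss = sofa_score(v, {"platelets": 90, "bilirubin": 40, "creatinine": 100})
    # MAP = 57 + (80-57)/3 = 64.7 < 70
    assert ss.sofa_components == {"respiration": 0, "coagulation": 2,
                                  "liver": 2, "cardiovascular": 1,
                                  "cns": 0, "renal": 0}
    assert ss.sofa_total == 5


def test_spo2_alone_can_meet_sepsis_threshold():
    ss = sofa_score(obs(spo2=90), {})
    assert ss.sofa_total == 2 and ss.sofa_components["respiration"] == 2


def test_all_missing_scores_zero_on_all_instruments():
    v = obs()
    assert news_score(v)[0] == 0
    assert qsofa_score(v) == 0
    assert sirs_score(v, None) == 0
    assert sofa_score(v, {}).sofa_total == 0


# --- properties ------------------------------------------------------------

_vitals = st.builds(
    obs,
    respiratory_rate=st.one_of(st.none(), st.floats(4, 60)),
    spo2=st.one_of(st.none(), st.floats(50, 100)),
    supplemental_oxygen=st.one_of(st.none(), st.booleans()),
    temperature=st.one_of(st.none(), st.floats(30, 43)),
    systolic_bp=st.one_of(st.none(), st.floats(40, 260)),
    diastolic_bp=st.one_of(st.none(), st.floats(20, 140)),
    heart_rate=st.one_of(st.none(), st.floats(20, 200)),
    avpu=st.one_of(st.none(), st.sampled_from(list(AVPU))),
    gcs=st.one_of(st.none(), st.integers(3, 15)),
)


@settings(max_examples=300, derandomize=True)
@given(v=_vitals, wcc=st.one_of(st.none(), st.floats(0, 40)))
def test_score_ranges(v, wcc):
    assert 0 <= news_score(v)[0] <= 20
    assert 0 <= qsofa_score(v) <= 3
    assert 0 <= sirs_score(v, wcc) <= 4
    ss = sofa_score(v, {})
    assert 0 <= ss.sofa_total <= 24
    assert all(0 <= c <= 4 for c in ss.sofa_components.values())
    assert ss.sofa_total == sum(ss.sofa_components.values())


# midpoint of each parameter's zero-point band; "worsening" moves away from it
_NORMAL_MID = {"respiratory_rate": 16.0, "spo2": 98.0, "temperature": 37.0,
               "systolic_bp": 165.0, "heart_rate": 70.0}
_BOUNDS = {"respiratory_rate": (0, 80), "spo2": (0, 100),
           "temperature": (25, 45), "systolic_bp": (0, 300),
           "heart_rate": (0, 250)}


@settings(max_examples=300, derandomize=True)
@given(v=_vitals, delta=st.floats(0.1, 40))
def test_news_monotone_when_worsening_each_parameter(v, delta):
    """Moving any parameter further from its normal band never lowers
    that parameter's NEWS contribution (SpO2 only worsens downward)."""
    import dataclasses
    _, base_pts = news_score(v)
    for name, mid in _NORMAL_MID.items():
        val = getattr(v, name)
        if val is None:
            continue
        sign = -1.0 if (name == "spo2" or val < mid) else 1.0
        lo, hi = _BOUNDS[name]
        new = min(max(val + sign * delta, lo), hi)
        kw = {f.name: getattr(v, f.name) for f in dataclasses.fields(v)}
        kw[name] = new
        _, new_pts = news_score(VitalsObservation(**kw))
        assert new_pts.get(name, 0) >= base_pts.get(name, 0)
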