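"""Preprocessing: specific-gravity correction, sunrise, times, exclusions."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortrhythm import preprocess as pp


# ---------------------------------------------------------------------------
# specific gravity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw,sg,target,expected", [
    (100_000, 1.020, 1.020, 100_000),   # identity at the target gravity
    (100_000, 1.010, 1.020, 200_000),
    (50_000, 1.030, 1.015, 25_000),
])
def test_sg_correction_examples(raw, sg, target, expected):
    assert pp.correct_specific_gravity(raw, sg, target) == pytest.approx(expected)


@pytest.mark.parametrize("sg,target", [(1.000, 1.02), (0.999, 1.02), (1.01, 1.0)])
def test_sg_correction_rejects_degenerate_gravity(sg, target):
    with pytest.raises(pp.InvalidGravityError):
        pp.correct_specific_gravity(1000.0, sg, target)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(raw=st.floats(1e2, 1e6), sg=st.floats(1.002, 1.05),
       target=st.floats(1.002, 1.05), scale=st.floats(0.1, 10))
def test_sg_correction_scaling_properties(raw, sg, target, scale):
    base = pp.correct_specific_gravity(raw, sg, target)
    # multiplicative in raw value
    assert pp.correct_specific_gravity(raw * scale, sg, target) == \
        pytest.approx(base * scale, rel=1e-12)
    # doubling (sg - 1) halves the output
    assert pp.correct_specific_gravity(raw, 1 + 2 * (sg - 1), target) == \
        pytest.approx(base / 2, rel=1e-12)


def test_population_sg_and_fixed_point():
    assert pp.compute_population_sg([1.010, 1.020, 1.030]) == pytest.approx(1.020)
    assert pp.compute_population_sg([1.015]) == pytest.approx(1.015)
    rng = np.random.default_rng(3)
    sgs = rng.uniform(1.005, 1.035, size=1000)
    assert pp.compute_population_sg(sgs) == pytest.approx(1.020, abs=3e-4)
    # a sample whose gravity equals the population mean is left unchanged
    target = pp.compute_population_sg(sgs)
    assert pp.correct_specific_gravity(5e5, target, target) == pytest.approx(5e5)
    with pytest.raises(pp.EmptyInputError):
        pp.compute_population_sg([])


# ---------------------------------------------------------------------------
# sunrise
# ---------------------------------------------------------------------------

def _spencer_sunrise_hour(lat, lon, tz, date):
    """Independent solar oracle: Spencer Fourier-series declination and
    equation of time (a different formulation than the implementation)."""
    doy = date.timetuple().tm_yday
    g = 2 * math.pi / 365 * (doy - 1 + 0.5)
    decl = (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    eqtime = 229.18 * (0.000075 + 0.001868 * math.cos(g)
                       - 0.032077 * math.sin(g) - 0.014615 * math.cos(2 * g)
                       - 0.040849 * math.sin(2 * g))
    latr = math.radians(lat)
    cos_ha = (math.cos(math.radians(90.833)) / (math.cos(latr) * math.cos(decl))
              - math.tan(latr) * math.tan(decl))
    ha = math.degrees(math.acos(cos_ha))
    utc_min = 720 - 4 * (lon + ha) - eqtime
    return utc_min / 60.0 + tz


def test_sunrise_equator_equinox():
    ctx = pp.SolarContext(0.0, 0.0, 0.0, dt.date(2023, 3, 20))
    h = pp.sunrise_hour(ctx)
    assert abs(h - 6.0) < 10 / 60  # ~06:00 local solar time


def test_sunrise_matches_independent_oracle_bolivia():
    ctx = pp.SolarContext(-14.9, -66.8, -4.0, dt.date(2023, 10, 15))
    ours = pp.sunrise_hour(ctx)
    oracle = _spencer_sunrise_hour(-14.9, -66.8, -4.0, dt.date(2023, 10, 15))
    assert abs(ours - oracle) * 60 < 5


def test_sunrise_oracle_agreement_across_tropics():
    rng = np.random.default_rng(11)
    for _ in range(100):
        lat = rng.uniform(-23, 23)
        lon = rng.uniform(-80, -40)
        date = dt.date(2023, 1, 1) + dt.timedelta(days=int(rng.integers(0, 365)))
        ours = pp.sunrise_hour(pp.SolarContext(lat, lon, -4.0, date))
        oracle = _spencer_sunrise_hour(lat, lon, -4.0, date)
        assert abs(ours - oracle) * 60 < 5, (lat, lon, date)


def test_sunrise_polar_day_errors():
    with pytest.raises(pp.NoSunriseError):
        pp.compute_sunrise(pp.SolarContext(80.0, 0.0, 0.0, dt.date(2023, 6, 21)))


# ---------------------------------------------------------------------------
# relative times
# ---------------------------------------------------------------------------

def _sample_frame(rows):
    return pd.DataFrame(rows, columns=pp.SAMPLE_COLUMNS)


@pytest.fixture()
def two_sample_day(study_config):
    return _sample_frame([
        ("A", "1", "2023-10-15", "", 1, 2e5, 1.02, 0),
        ("A", "1", "2023-10-15", "14:30", 0, 1e5, 1.02, 0),
    ])


def test_relative_times(two_sample_day, study_config):
    out = pp.assign_relative_times(two_sample_day, study_config)
    rise = pp.sunrise_hour(pp.SolarContext(
        *study_config.communities["1"], -4.0, dt.date(2023, 10, 15)))
    assert out["rel_time_h"].iloc[0] == 0.0
    assert out["rel_time_h"].iloc[1] == pytest.approx(14.5 - rise)
    assert out["rel_time_h"].iloc[1] > 0


def test_relative_time_errors(study_config):
    before_sunrise = _sample_frame([
        ("A", "1", "2023-10-15", "", 1, 2e5, 1.02, 0),
        ("A", "1", "2023-10-15", "05:00", 0, 1e5, 1.02, 0)])
    with pytest.raises(pp.NegativeTimeError):
        pp.assign_relative_times(before_sunrise, study_config)
    missing_clock = _sample_frame([
        ("A", "1", "2023-10-15", "", 1, 2e5, 1.02, 0),
        ("A", "1", "2023-10-15", "", 0, 1e5, 1.02, 0)])
    with pytest.raises(pp.MissingTimeError):
        pp.assign_relative_times(missing_clock, study_config)
    two_mornings = _sample_frame([
        ("A", "1", "2023-10-15", "", 1, 2e5, 1.02, 0),
        ("A", "1", "2023-10-15", "", 1, 1e5, 1.02, 0)])
    with pytest.raises(ValueError):
        pp.assign_relative_times(two_mornings, study_config)


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def _toy_tables():
    participants = pd.DataFrame({
        "participant_id": ["A", "B", "C", "D"],
        "gender": ["woman", "man", "woman", "man"],
        "age_years": [30.0, np.nan, 40.0, 50.0],
        "community_id": ["1"] * 4,
        "translator_id": ["T1"] * 4,
        "pregnant": [1, 0, 0, 0],
    })
    samples = pd.DataFrame({
        "participant_id": ["A", "A", "B", "C", "D"],
        "community_id": ["1"] * 5,
        "date": ["2023-10-01"] * 5,
        "clock_time": [""] * 5,
        "is_first_morning": [1, 0, 1, 1, 1],
        "raw_cortisol_pg_ml": [1e5] * 5,
        "specific_gravity": [1.02] * 5,
        "censored_high": [0] * 5,
    })
    questionnaire = pd.DataFrame({
        "participant_id": ["A", "B", "C", "D"],
        "health_vs_others": [2, 2, np.nan, 2],
        "worry_food": [1, 1, 1, 1], "day_without_food": [1, 1, 1, 1],
        "hunger_sleep": [1, 1, 1, 1], "conflict_spouse": [1, 1, 1, 1],
        "conflict_children": [1, 1, 1, 1], "rumination_sleep": [1, 1, 1, 1],
        "in_debt": [0, 0, 0, 1],
    })
    return participants, samples, questionnaire


def test_exclusions_model0_vs_model1():
    participants, samples, questionnaire = _toy_tables()
    p0, s0, _, log0 = pp.apply_exclusions(participants, samples,
                                          questionnaire, "model0")
    # pregnant (A) and missing-age (B) go; incomplete questionnaire (C) stays
    assert sorted(p0["participant_id"]) == ["C", "D"]
    assert sorted(s0["participant_id"]) == ["C", "D"]
    assert sorted(log0["reason"]) == ["missing_age", "pregnant"]

    p1, _, q1, log1 = pp.apply_exclusions(participants, samples,
                                          questionnaire, "model1")
    assert sorted(p1["participant_id"]) == ["D"]
    assert sorted(log1["reason"]) == ["incomplete_questionnaire",
                                      "missing_age", "pregnant"]
    assert list(q1["participant_id"]) == ["D"]


def test_exclusions_idempotent_and_identity():
    participants, samples, questionnaire = _toy_tables()
    p1, s1, q1, _ = pp.apply_exclusions(participants, samples, questionnaire,
                                        "model1")
    p2, s2, q2, log2 = pp.apply_exclusions(p1, s1, q1, "model1")
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(s1, s2)
    assert log2.empty

    clean = participants.assign(pregnant=0, age_years=30.0)
    p3, s3, _, log3 = pp.apply_exclusions(clean, samples, questionnaire,
                                          "model0")
    assert len(p3) == len(clean) and len(s3) == len(samples) and log3.empty


def test_exclusions_orphan_samples_error():
    participants, samples, questionnaire = _toy_tables()
    bad = pd.concat([samples, samples.iloc[[0]].assign(participant_id="ZZ")])
    with pytest.raises(pp.ReferentialIntegrityError):
        pp.apply_exclusions(participants, bad, questionnaire, "model0")


def test_standardize_age():
    z = pp.standardize_age([20, 30, 40, 70])
    assert np.mean(z) == pytest.approx(0, abs=1e-12)
    assert np.std(z) == pytest.approx(1, abs=1e-12)


def test_prepare_model_data_invariants(small_model0_data):
    data = small_model0_data
    assert data.y.min() > 0
    first = data.rel_time_h == 0
    assert np.all(data.rel_time_h[~first] > 0)
    assert data.age_z.mean() == pytest.approx(0, abs=1e-10)
    assert np.std(data.age_z) == pytest.approx(1, abs=1e-10)
    assert data.pid_index.max() == data.n_participants - 1
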