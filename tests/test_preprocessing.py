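"""Deterministic preprocessing: drift medians, transit, phases, design."""

import math

import numpy as np
import pandas as pd
import pytest

from sealipid import (CapturePhysiology, ModelSpec, back_calculate_arrival_mass,
                      build_design, median_daily_drift, non_lipid_series,
                      running_transit, segment_phases)
from sealipid.preprocessing import daily_positions


# ---------------------------------------------------------------------------
# drift summaries
# ---------------------------------------------------------------------------

def _dives(records):
    return pd.DataFrame(records, columns=["id", "timestamp", "drift_rate_mps"])


def test_median_daily_drift_cases():
    df = _dives([
        ("a", "2005-06-01T03:00:00", -0.2),             # single dive day
        ("a", "2005-06-03T01:00:00", -0.3),             # even-count day
        ("a", "2005-06-03T02:00:00", -0.1),
        ("a", "2005-06-03T03:00:00", 0.2),
        ("a", "2005-06-03T04:00:00", 0.4),
    ])
    out = median_daily_drift(df)
    assert out.loc[out.day_index == 0, "median_drift_rate"].item() == pytest.approx(-0.2)
    assert out.loc[out.day_index == 0, "n_drift_dives"].item() == 1
    # even count: mean of the two middle values
    assert out.loc[out.day_index == 2, "median_drift_rate"].item() == pytest.approx(0.05)
    assert out.loc[out.day_index == 2, "n_drift_dives"].item() == 4
    # dive-free day: absent median, h = 0
    assert out.loc[out.day_index == 1, "median_drift_rate"].isna().all()
    assert out.loc[out.day_index == 1, "n_drift_dives"].item() == 0


def test_median_daily_drift_rejects_nonfinite_with_warning():
    df = _dives([("a", "2005-06-01T03:00:00", -0.2),
                 ("a", "2005-06-01T04:00:00", float("nan"))])
    with pytest.warns(UserWarning):
        out = median_daily_drift(df)
    assert out["n_drift_dives"].iloc[0] == 1


# ---------------------------------------------------------------------------
# transit
# ---------------------------------------------------------------------------

def test_daily_transit_stationary_and_segments():
    one_deg = math.pi * 6371.0 / 180.0
    track = pd.DataFrame({
        "id": ["a"] * 4,
        "timestamp": ["2005-06-01T00:00", "2005-06-01T12:00",
                      "2005-06-02T00:00", "2005-06-02T12:00"],
        "lon": [0.0, 0.0, 0.5, 1.0],
        "lat": [0.0, 0.0, 0.0, 0.0],
    })
    daily = daily_positions(track).set_index("day_index")
    assert daily.loc[0, "transit_km"] == pytest.approx(0.0)          # stationary
    # two half-degree equatorial segments end on day 1: additivity
    assert daily.loc[1, "transit_km"] == pytest.approx(one_deg, rel=1e-9)


def test_running_transit_edges_and_centre():
    assert np.allclose(running_transit([7.0] * 9), 7.0)
    out = running_transit([0, 0, 100, 0, 0])
    assert out[2] == pytest.approx(20.0)
    # shorter than the window: plain mean everywhere it can reach
    short = running_transit([10.0, 20.0, 30.0])
    assert short[1] == pytest.approx(20.0)
    with pytest.raises(ValueError):
        running_transit([])


# ---------------------------------------------------------------------------
# phase segmentation
# ---------------------------------------------------------------------------

def _ramp_fixture():
    dist = np.concatenate([np.linspace(10, 100, 10), np.full(10, 100.0),
                           np.linspace(90, 10, 10)])
    rt = np.array([50.0] * 10 + [10.0] * 10 + [50.0] * 10)
    return dist, rt


def test_segment_phases_three_blocks():
    dist, rt = _ramp_fixture()
    phases = segment_phases(dist, rt, foraging_threshold_km=30.0)
    assert list(phases[:10]) == ["outbound"] * 10
    assert list(phases[10:20]) == ["foraging"] * 10
    assert list(phases[20:]) == ["return"] * 10


@pytest.mark.parametrize("threshold", [25.0, 40.0])
def test_segment_phases_threshold_insensitive_on_ramp(threshold):
    """Transit values of 50 and 10 straddle no threshold in 25-40."""
    dist, rt = _ramp_fixture()
    phases = segment_phases(dist, rt, foraging_threshold_km=threshold)
    assert list(phases) == (["outbound"] * 10 + ["foraging"] * 10
                            + ["return"] * 10)


def test_segment_phases_never_triggering_warns_all_outbound():
    dist = np.linspace(0, 290, 30)
    rt = np.full(30, 50.0)
    with pytest.warns(UserWarning):
        phases = segment_phases(dist, rt, 30.0)
    assert set(phases) == {"outbound"}


def test_segment_phases_reproducible_and_short_series_errors():
    dist, rt = _ramp_fixture()
    a = segment_phases(dist, rt, 30.0)
    b = segment_phases(dist, rt, 30.0)
    assert (a == b).all()
    with pytest.raises(ValueError):
        segment_phases([1.0, 2.0], [1.0, 2.0], 30.0)


# ---------------------------------------------------------------------------
# arrival-mass back-calculation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mass, days, rate, expected", [
    (300.0, 0, 4.5, 300.0),
    (300.0, 5, 4.0, 320.0),
    (300.0, 5, 0.0, 300.0),
])
def test_back_calculate_arrival_mass(mass, days, rate, expected):
    assert back_calculate_arrival_mass(mass, days, rate) == pytest.approx(expected)


def test_back_calculate_rejects_negative():
    with pytest.raises(ValueError):
        back_calculate_arrival_mass(300.0, -1, 4.0)


# ---------------------------------------------------------------------------
# non-lipid tissue forms
# ---------------------------------------------------------------------------

def test_non_lipid_series_endpoints_and_shapes():
    T = 90
    r = {f: non_lipid_series(f, T, 300.0, 330.0) for f in range(1, 7)}
    for f, series in r.items():
        assert series[0] == pytest.approx(300.0)
        assert series[-1] == pytest.approx(330.0)
        assert np.all(series > 0)
    # form 1 exactly linear
    assert np.allclose(r[1], np.linspace(300.0, 330.0, T + 1))
    # form 6: all gain in the first third, flat after
    k1 = math.ceil(T / 3)
    assert r[6][k1] == pytest.approx(330.0)
    assert np.allclose(r[6][k1:], 330.0)
    assert np.all(np.diff(r[6][:k1]) > 0)


def test_non_lipid_series_pup_accrual_forms():
    """Forms 2, 3, 5 add the pup's mass over the final third; 1, 4, 6 don't."""
    T = 90
    k2 = math.ceil(2 * T / 3)
    with_pup = {f: non_lipid_series(f, T, 300.0, 330.0, pup_birth_mass_kg=40.0)
                for f in range(1, 7)}
    for f in (2, 3, 5):
        assert with_pup[f][-1] == pytest.approx(330.0)
        # before the last third the series sits below its pup-free target ramp
        assert with_pup[f][k2] == pytest.approx(
            non_lipid_series(f, T, 300.0, 290.0)[k2], rel=1e-9)
    for f in (1, 4, 6):
        assert np.allclose(with_pup[f], non_lipid_series(f, T, 300.0, 330.0))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _design_inputs(n_days=10):
    rows = []
    for sid, loc in [("a", "coastal"), ("b", "pelagic"), ("c", "nepacific")]:
        for t in range(n_days + 1):
            phase = ("outbound" if t < 3 else "foraging" if t < 8 else "return")
            rows.append({"id": sid, "day_index": t, "lon": 0.0, "lat": 0.0,
                         "transit_km": 10.0 + t, "transit5d_km": 10.0 + t,
                         "dist_colony_km": 50.0 * t, "phase": phase,
                         "state_index": float(t % 2)})
    track_days = pd.DataFrame(rows)
    drift = pd.DataFrame([{"id": sid, "day_index": t,
                           "median_drift_rate": -0.2, "n_drift_dives": 3 + t % 4}
                          for sid in "abc" for t in range(n_days + 1)])
    phys = [CapturePhysiology(sid, 400.0, 25.0, 420.0, 28.0, loc)
            for sid, loc in [("a", "coastal"), ("b", "pelagic"), ("c", "nepacific")]]
    return track_days, drift, phys


def test_design_location_phase_coding():
    """3 locations x 3 phases give 8 indicators; the reference cell row
    (coastal animal in the foraging phase) is all zeros."""
    track_days, drift, phys = _design_inputs()
    spec = ModelSpec(standardize=False)
    design, meta = build_design(track_days, drift, phys, spec)
    assert len(meta["location_phase_columns"]) == 8
    ref_rows = design[(design["id"] == "a") & (design["day_index"] == 5)]
    assert ref_rows[meta["location_phase_columns"]].to_numpy().sum() == 0
    other = design[(design["id"] == "b") & (design["day_index"] == 5)]
    assert other["pelagic:foraging"].item() == 1.0
    assert other[meta["location_phase_columns"]].to_numpy().sum() == 1.0


def test_design_row_count_and_duplicate_detection():
    track_days, drift, phys = _design_inputs(n_days=10)
    design, _ = build_design(track_days, drift, phys, ModelSpec())
    # one row per individual-day 0..T-1
    assert len(design) == 3 * 10
    dup = pd.concat([track_days, track_days.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError):
        build_design(dup, drift, phys, ModelSpec())


def test_design_standardisation_is_recorded():
    track_days, drift, phys = _design_inputs()
    design, meta = build_design(track_days, drift, phys, ModelSpec(standardize=True))
    for col in ("transit", "n_drift_dives"):
        assert col in meta["scaling"]
        assert design[col].mean() == pytest.approx(0.0, abs=1e-12)
    # indicators and intercept never scaled
    assert "intercept" not in meta["scaling"]
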