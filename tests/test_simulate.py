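"""Synthetic-data generator: construction invariants and round trips."""

import numpy as np
import pandas as pd
import pytest

from sealipid import (SimulationConfig, simulate_population, segment_phases,
                      prepare)
from sealipid.geo import haversine_km
from sealipid.simulate import NES_TEMPLATE, SES_TEMPLATE, simulate_track


@pytest.fixture(scope="module")
def pop():
    return simulate_population(SimulationConfig(n_individuals=5,
                                                trip_length_days=80, seed=42))


def test_track_geometry_construction():
    cfg = SimulationConfig(n_individuals=1, trip_length_days=100, seed=3)
    rng = np.random.default_rng(3)
    track = simulate_track(cfg, rng, "pelagic")
    colony = NES_TEMPLATE.colony
    # return endpoint lands near the colony
    end = track.iloc[-1]
    assert haversine_km(end["lon"], end["lat"], colony[0], colony[1]) < 50.0
    # outbound mean transit exceeds foraging mean transit
    out_t = track.loc[track["phase"] == "outbound", "transit_km"].mean()
    for_t = track.loc[track["phase"] == "foraging", "transit_km"].mean()
    assert out_t > for_t
    # emitted transit is exactly the haversine of successive positions
    lon, lat = track["lon"].to_numpy(), track["lat"].to_numpy()
    seg = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    assert np.allclose(track["transit_km"].to_numpy()[1:], seg, atol=1e-9)


def test_phase_segmentation_recovers_generating_labels():
    """Rule-based segmentation at a 30 km/day threshold agrees with the
    generating phase labels on at least 95% of days."""
    cfg = SimulationConfig(n_individuals=1, trip_length_days=120, seed=5)
    rng = np.random.default_rng(11)
    agree = []
    for loc in ("pelagic", "nepacific"):
        track = simulate_track(cfg, rng, loc)
        labels = segment_phases(track["dist_colony_km"].to_numpy(),
                                track["transit5d_km"].to_numpy(), 30.0)
        agree.append(np.mean(labels == track["phase"].to_numpy()))
    assert np.mean(agree) >= 0.95


def test_physiology_and_nonlipid_construction(pop):
    for phys in pop.physiology:
        r0 = phys.departure_mass_kg * (1 - phys.departure_lipid_pct / 100)
        sid = phys.individual_id
        ds = pop.dataset()
        seal = next(s for s in ds.seals if s.individual_id == sid)
        assert seal.R[0] == pytest.approx(r0, rel=1e-9)
        # form 6: R flat over the last two thirds
        third = -(2 * len(seal.R) // 3)
        assert np.allclose(np.diff(seal.R[third:]), 0.0)


def test_same_seed_reproduces_byte_identical_csv(tmp_path, pop):
    cfg = SimulationConfig(n_individuals=3, trip_length_days=40, seed=7)
    for d in ("a", "b"):
        simulate_population(cfg).to_csv(tmp_path / d)
    for name in ("dives", "track", "captures", "states"):
        assert ((tmp_path / "a" / f"{name}.csv").read_bytes()
                == (tmp_path / "b" / f"{name}.csv").read_bytes())
    assert ((tmp_path / "a" / "truth.json").read_bytes()
            == (tmp_path / "b" / "truth.json").read_bytes())


def test_observation_noise_matches_tau2():
    """Empirical variance of D around its generating mean on h = 1 days
    approaches tau2 (the spread grows as 1/h, so h = 1 days carry it)."""
    cfg = SimulationConfig(n_individuals=8, trip_length_days=150, seed=13,
                           overrides={"dive_rate_mean": 1.5})
    p = simulate_population(cfg)
    resids = []
    t = cfg.template()
    for phys in p.physiology:
        sid = phys.individual_id
        d = p.drift[p.drift["id"] == sid]
        L = np.asarray(p.truth["latent"][sid])
        ds = p.dataset()
        seal = next(s for s in ds.seals if s.individual_id == sid)
        h1 = d["n_drift_dives"].to_numpy() == 1
        mu = t.alpha[0] + t.alpha[1] * L[h1] / seal.R[h1]
        resids.append(d["median_drift_rate"].to_numpy()[h1] - mu)
    r = np.concatenate(resids)
    assert len(r) > 100
    assert np.var(r) == pytest.approx(t.tau2, rel=0.35)


def test_zero_inflation_raises_missing_day_fraction():
    fracs = []
    for zi in (0.0, 0.3, 0.6):
        cfg = SimulationConfig(n_individuals=4, trip_length_days=60, seed=17,
                               overrides={"zero_inflation": zi})
        p = simulate_population(cfg)
        fracs.append(float((p.drift["n_drift_dives"] == 0).mean()))
    assert fracs[0] < fracs[1] < fracs[2]


def test_ses_template_dives_less_than_nes():
    nes = simulate_population(SimulationConfig(n_individuals=6, seed=19,
                                               trip_length_days=60))
    ses = simulate_population(SimulationConfig(n_individuals=6, seed=19,
                                               trip_length_days=60,
                                               species="SES"))
    assert (ses.drift["n_drift_dives"].mean()
            < nes.drift["n_drift_dives"].mean())
    assert (ses.drift["n_drift_dives"] == 0).mean() \
        > (nes.drift["n_drift_dives"] == 0).mean()


def test_emitted_files_round_trip_through_preprocessing(pop):
    """The CSV-dialect frames feed the full preprocessing pipeline; the
    recovered daily drift summaries match the generating ones exactly
    (the per-dive records are built to preserve the daily median)."""
    frames = pop.to_frames()
    model_ready, ds = prepare(frames["dives"], frames["track"],
                              frames["captures"], frames["states"],
                              spec=pop.config.model_spec(standardize=False),
                              colony=pop.config.template().colony)
    assert ds.n_individuals == pop.config.n_individuals
    merged = model_ready.merge(pop.drift, on=["id", "day_index"],
                               suffixes=("", "_gen"))
    both = merged.dropna(subset=["median_drift_rate", "median_drift_rate_gen"])
    assert np.allclose(both["median_drift_rate"],
                       both["median_drift_rate_gen"], atol=1e-9)
    assert (merged["n_drift_dives"] == merged["n_drift_dives_gen"]).all()
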