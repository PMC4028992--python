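"""Turn per-dive and per-position telemetry into the daily model-ready dataset.

The pipeline condenses raw tables into one row per individual-day:

* median daily drift rate D and drift-dive count h;
* daily transit and its 5-day running mean from the positions;
* distance to colony and the three-phase outbound/foraging/return
  segmentation of the track;
* the fixed non-lipid tissue series R (six candidate functional forms);
* the process-model design matrix with location x phase interaction
  coding and a latent-dependent lipid:lean ratio column.

Day boundaries are UTC calendar days and day_index 0 is the departure
day, matching the daily time step of the process model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ModelSpec
from .geo import haversine_km

__all__ = [
    "CapturePhysiology",
    "SealArrays",
    "SealDataset",
    "median_daily_drift",
    "daily_positions",
    "daily_transit",
    "running_transit",
    "distance_to_colony",
    "segment_phases",
    "back_calculate_arrival_mass",
    "non_lipid_series",
    "build_design",
    "build_dataset",
    "prepare",
]

PHASES = ("outbound", "foraging", "return")


# ---------------------------------------------------------------------------
# capture physiology
# ---------------------------------------------------------------------------

@dataclass
class CapturePhysiology:
    """Mass and lipid measurements at departure and arrival for one trip."""

    individual_id: str
    departure_mass_kg: float
    departure_lipid_pct: float
    arrival_mass_kg: float
    arrival_lipid_pct: float
    foraging_location: str = ""
    pup_birth_mass_kg: float = 0.0
    days_between_arrival_and_weighing: int = 0

    def __post_init__(self):
        for m in (self.departure_mass_kg, self.arrival_mass_kg):
            if not m > 0:
                raise ValueError("masses must be positive")
        for p in (self.departure_lipid_pct, self.arrival_lipid_pct):
            if not 0 < p < 100:
                raise ValueError("lipid percentages must be in (0, 100)")

    @property
    def departure_lipid_kg(self) -> float:
        return self.departure_mass_kg * self.departure_lipid_pct / 100.0

    @property
    def arrival_lipid_kg(self) -> float:
        return self.arrival_mass_kg * self.arrival_lipid_pct / 100.0

    @property
    def departure_nonlipid_kg(self) -> float:
        return self.departure_mass_kg - self.departure_lipid_kg

    @property
    def arrival_nonlipid_kg(self) -> float:
        return self.arrival_mass_kg - self.arrival_lipid_kg


def back_calculate_arrival_mass(measured_mass_kg: float,
                                days_since_birth: float,
                                daily_loss_rate_kg: float) -> float:
    """Arrival mass extrapolated back from a post-partum weighing.

    Mothers are typically not weighed until days after giving birth, so
    the measured mass understates arrival mass by the daily on-land loss
    rate times the delay.  The loss-rate coefficient comes from on-land
    weight-loss regressions and is supplied by the caller.
    """
    if measured_mass_kg < 0 or days_since_birth < 0 or daily_loss_rate_kg < 0:
        raise ValueError("inputs must be non-negative")
    return measured_mass_kg + days_since_birth * daily_loss_rate_kg


# ---------------------------------------------------------------------------
# drift summaries
# ---------------------------------------------------------------------------

def median_daily_drift(dives: pd.DataFrame,
                       departure: Optional[dict] = None,
                       n_days: Optional[dict] = None) -> pd.DataFrame:
    """Per-day median drift rate and drift-dive count per individual.

    Parameters
    ----------
    dives
        Per-dive records with columns ``id``, ``timestamp`` (ISO-8601 or
        datetime), ``drift_rate_mps`` and optionally ``is_drift_dive``.
        Non-drift dives and non-finite rates are dropped (the latter with
        a warning).
    departure
        Mapping id -> departure date (day_index 0).  Defaults to the
        first dive date per individual.
    n_days
        Mapping id -> trip length T; output covers day_index 0..T with
        h = 0 / absent median on dive-free days.

    Returns
    -------
    DataFrame with columns id, day_index, median_drift_rate, n_drift_dives.
    """
    d = dives.copy()
    if "is_drift_dive" in d.columns:
        d = d[d["is_drift_dive"].astype(bool)]
    bad = ~np.isfinite(d["drift_rate_mps"].to_numpy(dtype=float))
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} dive records with non-finite drift rate")
        d = d[~bad]
    ts = pd.to_datetime(d["timestamp"], utc=True, format="ISO8601")
    d = d.assign(_date=ts.dt.floor("D").dt.tz_localize(None))

    out = []
    for sid, g in d.groupby("id", sort=True):
        day0 = (pd.Timestamp(departure[sid]) if departure and sid in departure
                else g["_date"].min())
        day_index = (g["_date"] - day0).dt.days
        agg = (g.assign(day_index=day_index)
                .groupby("day_index")["drift_rate_mps"]
                .agg(median_drift_rate="median", n_drift_dives="size")
                .reset_index())
        top = int(n_days[sid]) if n_days and sid in n_days else int(agg["day_index"].max())
        full = pd.DataFrame({"day_index": np.arange(top + 1)})
        agg = full.merge(agg, on="day_index", how="left")
        agg["n_drift_dives"] = agg["n_drift_dives"].fillna(0).astype(int)
        agg.insert(0, "id", sid)
        out.append(agg)
    res = pd.concat(out, ignore_index=True)
    # invariant: h == 0 exactly when the median is absent
    assert ((res["n_drift_dives"] == 0) == res["median_drift_rate"].isna()).all()
    return res


# ---------------------------------------------------------------------------
# track geometry
# ---------------------------------------------------------------------------

def daily_positions(track: pd.DataFrame,
                    departure: Optional[dict] = None) -> pd.DataFrame:
    """Collapse a (possibly multi-fix-per-day) track to one row per day.

    Emits per individual-day the mean position and the daily transit --
    the summed great-circle lengths of position segments ending on that
    day.  Days with no fixes are absent from the output (transit flagged
    absent, not zero, downstream).
    """
    t = track.copy()
    ts = pd.to_datetime(t["timestamp"], utc=True, format="ISO8601")
    t = t.assign(_ts=ts, _date=ts.dt.floor("D").dt.tz_localize(None))
    out = []
    for sid, g in t.groupby("id", sort=True):
        g = g.sort_values("_ts")
        day0 = (pd.Timestamp(departure[sid]) if departure and sid in departure
                else g["_date"].min())
        day_index = ((g["_date"] - day0).dt.days).to_numpy()
        lon = g["lon"].to_numpy(dtype=float)
        lat = g["lat"].to_numpy(dtype=float)
        seg = np.zeros(len(g))
        if len(g) > 1:
            seg[1:] = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        df = pd.DataFrame({"day_index": day_index, "lon": lon, "lat": lat, "seg": seg})
        daily = df.groupby("day_index").agg(
            lon=("lon", "mean"), lat=("lat", "mean"), transit_km=("seg", "sum")
        ).reset_index()
        daily.insert(0, "id", sid)
        out.append(daily)
    return pd.concat(out, ignore_index=True)


def daily_transit(track: pd.DataFrame, departure: Optional[dict] = None) -> pd.Series:
    """Daily transit (km) per individual-day; see :func:`daily_positions`."""
    daily = daily_positions(track, departure)
    return daily.set_index(["id", "day_index"])["transit_km"]


def running_transit(transit: Sequence[float], window: int = 5) -> np.ndarray:
    """Centred running mean of a daily transit series.

    At the series edges the window shrinks to the available days; a
    series shorter than the window therefore gets the plain mean at the
    centre.  ``window`` must be odd and positive.
    """
    x = pd.Series(np.asarray(transit, dtype=float))
    if x.empty:
        raise ValueError("empty transit series")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    return x.rolling(window, center=True, min_periods=1).mean().to_numpy()


def distance_to_colony(lon, lat, colony_lon, colony_lat) -> np.ndarray:
    return np.atleast_1d(haversine_km(lon, lat, colony_lon, colony_lat))


def segment_phases(dist_colony: Sequence[float],
                   running_transit: Sequence[float],
                   foraging_threshold_km: float = 30.0,
                   lookahead: int = 3,
                   tol_km: float = 0.0,
                   overrides: Optional[tuple] = None) -> np.ndarray:
    """Split a trip into outbound / foraging / return phases.

    Foraging begins at the first day where the running transit drops
    below ``foraging_threshold_km`` while the distance to colony is still
    increasing or plateaued.  The return leg begins at the last "fresh
    descent": a day on which distance to colony starts decreasing
    (strictly, beyond ``tol_km``) and keeps decreasing over the next
    ``lookahead`` days.  Per-individual threshold values in the 25-40
    km/day range are accepted; ``overrides=(f_start, r_start)`` bypasses
    the rules entirely for manually assigned transitions.
    """
    dist = np.asarray(dist_colony, dtype=float)
    rt = np.asarray(running_transit, dtype=float)
    n = len(dist)
    if n != len(rt):
        raise ValueError("series length mismatch")
    if n < 3:
        raise ValueError("series too short to segment (< 3 days)")

    phases = np.array(["outbound"] * n, dtype=object)
    if overrides is not None:
        f_start, r_start = overrides
    else:
        f_start = None
        for t in range(1, n):
            if rt[t] < foraging_threshold_km and dist[t] >= dist[t - 1] - tol_km:
                f_start = t
                break
        if f_start is None:
            warnings.warn("no day satisfies the foraging rule; whole trip labelled outbound")
            return phases
        # fresh-descent days: step into t decreases and the previous step did not
        dec = dist[1:] < dist[:-1] - tol_km   # dec[k]: step k -> k+1 decreases
        r_start = None
        for t in range(f_start + 1, n - lookahead + 1):
            fresh = dec[t - 1] and (t - 2 < 0 or not dec[t - 2])
            sustained = all(dec[t - 1 + k] for k in range(min(lookahead, n - t)))
            if fresh and sustained:
                r_start = t
        if r_start is None:
            warnings.warn("no sustained decrease toward colony; no return phase assigned")
    phases[f_start:] = "foraging"
    if r_start is not None:
        phases[r_start:] = "return"
    return phases


# ---------------------------------------------------------------------------
# fixed non-lipid tissue series
# ---------------------------------------------------------------------------

# relative slope weights over (first, middle, last) third of the trip
_FORM_WEIGHTS = {
    1: (1.0, 1.0, 1.0),   # constant linear increase
    2: (1.0, 1.0, 1.0),   # linear, pup mass accrues in the final third
    3: (2.0, 1.0, 2.0),   # high - slow - high, pup in the final third
    4: (1.0, 0.0, 1.0),   # high - flat - high, no pup
    5: (1.0, 0.0, 1.0),   # as 4 but pup accrues in the final third
    6: (1.0, 0.0, 0.0),   # all gain in the first third, flat after
}
_FORMS_WITH_PUP = {2, 3, 5}


def non_lipid_series(form: int, n_days: int, departure_nonlipid_kg: float,
                     arrival_nonlipid_kg: float, pup_birth_mass_kg: float = 0.0
                     ) -> np.ndarray:
    """Fixed non-lipid tissue R_t (kg) for day_index 0..n_days.

    Piecewise-linear interpolation between the known departure and
    arrival non-lipid masses under one of six shapes.  Forms 2, 3 and 5
    accrue the pup's mass over the final third of the trip; form 6 puts
    the entire gain linearly over the first ceil(T/3) days and is flat
    after.
    """
    if form not in _FORM_WEIGHTS:
        raise ValueError("form must be in 1..6")
    T = int(n_days)
    if T < 1:
        raise ValueError("n_days must be >= 1")
    k1, k2 = math.ceil(T / 3), math.ceil(2 * T / 3)
    w1, w2, w3 = _FORM_WEIGHTS[form]
    t = np.arange(T + 1, dtype=float)
    # cumulative weight up to day t
    cum = (np.minimum(t, k1) * w1
           + np.clip(t - k1, 0.0, k2 - k1) * w2
           + np.clip(t - k2, 0.0, T - k2) * w3)
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate form weights")
    pup = pup_birth_mass_kg if form in _FORMS_WITH_PUP else 0.0
    base_target = arrival_nonlipid_kg - pup
    r = departure_nonlipid_kg + (base_target - departure_nonlipid_kg) * cum / total
    if pup > 0:
        ramp = np.clip(t - k2, 0.0, T - k2) / max(T - k2, 1)
        r = r + pup * ramp
    if np.any(r <= 0):
        raise ValueError("non-lipid series must stay positive")
    return r


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _location_phase_columns(locations: Sequence[str], reference_cell: tuple) -> list:
    cols = []
    for loc in locations:
        for ph in PHASES:
            if (loc, ph) == tuple(reference_cell):
                continue
            cols.append(f"{loc}:{ph}")
    return cols


def build_design(track_days: pd.DataFrame,
                 drift_summaries: pd.DataFrame,
                 physiology: Sequence[CapturePhysiology],
                 spec: ModelSpec) -> tuple:
    """Assemble the process-model design matrix.

    One row per individual-day t = 0..T-1 (the row governs the
    transition t -> t+1).  Location x phase cells are coded as indicator
    columns with the reference cell omitted; continuous covariates are
    optionally z-scored (scaling constants returned for back-transforms).
    The lipid:lean ratio column is a placeholder (zeros) flagged as
    latent-dependent: it is recomputed from the current latent lipid
    trajectory inside every density evaluation.

    Returns
    -------
    (design, meta): long DataFrame of design rows keyed by (id, day_index)
    and a dict with column names, random-effect / latent indices and
    scaling constants.
    """
    phys = {p.individual_id: p for p in physiology}
    merged = track_days.merge(
        drift_summaries[["id", "day_index", "n_drift_dives"]],
        on=["id", "day_index"], how="left")
    if merged.duplicated(["id", "day_index"]).any():
        raise ValueError("duplicate (individual, day) rows in inputs")

    locations = sorted({p.foraging_location for p in physiology if p.foraging_location})
    lp_cols = _location_phase_columns(locations, spec.reference_cell) \
        if spec.include_location_phase and locations else []

    frames = []
    for sid, g in merged.groupby("id", sort=True):
        g = g.sort_values("day_index")
        T = int(g["day_index"].max())
        g = g[g["day_index"] < T]  # rows govern transitions 0..T-1
        p = phys[sid]
        df = pd.DataFrame({"id": sid, "day_index": g["day_index"].to_numpy()})
        for col in spec.covariates:
            if col == "intercept":
                df[col] = 1.0
            elif col == "transit":
                src = "transit_km" if spec.transit_kind == "daily" else "transit5d_km"
                df[col] = g[src].to_numpy(dtype=float)
            elif col == "n_drift_dives":
                df[col] = g["n_drift_dives"].fillna(0).to_numpy(dtype=float)
            elif col == spec.latent_column:
                df[col] = 0.0  # filled from the latent state at sampling time
            elif col == "departure_lipid_pct":
                df[col] = p.departure_lipid_pct
            elif col == "state_index":
                s = g["state_index"] if "state_index" in g else pd.Series(0.0, index=g.index)
                df[col] = (s.map({"travelling": 0.0, "foraging": 1.0})
                           if s.dtype == object else s).astype(float).to_numpy()
            elif col in g.columns:
                df[col] = g[col].to_numpy(dtype=float)
            else:
                raise KeyError(f"unknown covariate column '{col}'")
        for c in lp_cols:
            loc, ph = c.split(":")
            if p.foraging_location and p.foraging_location not in locations:
                raise ValueError(f"unknown location level '{p.foraging_location}'")
            df[c] = ((p.foraging_location == loc) & (g["phase"].to_numpy() == ph)).astype(float)
        frames.append(df)
    design = pd.concat(frames, ignore_index=True)

    columns = [c for c in spec.covariates] + lp_cols
    scaling = {}
    if spec.standardize:
        skip = {"intercept", spec.latent_column} | set(lp_cols)
        for c in columns:
            if c in skip:
                continue
            v = design[c].to_numpy(dtype=float)
            m, s = float(np.nanmean(v)), float(np.nanstd(v))
            if s > 0:
                design[c] = (v - m) / s
                scaling[c] = (m, s)
    meta = {
        "columns": columns,
        "location_phase_columns": lp_cols,
        "random_effect_columns": list(spec.random_effects),
        "latent_column": spec.latent_column if spec.latent_column in columns else None,
        "scaling": scaling,
        "locations": locations,
    }
    return design, meta


# ---------------------------------------------------------------------------
# model-ready dataset
# ---------------------------------------------------------------------------

@dataclass
class SealArrays:
    """Model-ready arrays for one individual-trip (days 0..T)."""

    individual_id: str
    D: np.ndarray          # (T+1,) median daily drift rate, NaN on h==0 days
    h: np.ndarray          # (T+1,) drift-dive counts
    R: np.ndarray          # (T+1,) fixed non-lipid tissue, kg
    X: np.ndarray          # (T, p) design rows for transitions t -> t+1
    L0: float              # departure lipid, kg (fixed)
    LT: float              # arrival lipid, kg (fixed)
    cov_missing: Optional[np.ndarray] = None  # (T, p) boolean

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        self.h = np.asarray(self.h, dtype=int)
        self.R = np.asarray(self.R, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        T = self.X.shape[0]
        if len(self.D) != T + 1 or len(self.h) != T + 1 or len(self.R) != T + 1:
            raise ValueError("array length mismatch: need T+1 days and T design rows")
        if np.any(self.R <= 0):
            raise ValueError("non-lipid tissue must be positive")
        if not (self.L0 >= 0 and self.LT >= 0):
            raise ValueError("endpoint lipid masses must be non-negative")
        if self.cov_missing is None:
            self.cov_missing = ~np.isfinite(self.X)
        self.X = np.nan_to_num(self.X, nan=0.0)

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def obs_mask(self) -> np.ndarray:
        return (self.h > 0) & np.isfinite(self.D)


@dataclass
class SealDataset:
    """All observed quantities for a population of individual-trips."""

    seals: list
    columns: list
    spec: ModelSpec
    scaling: dict = field(default_factory=dict)
    locations: list = field(default_factory=list)

    def __post_init__(self):
        self.re_idx = np.array([self.columns.index(c) for c in self.spec.random_effects],
                               dtype=int)
        lc = self.spec.latent_column
        self.latent_idx = self.columns.index(lc) if lc in self.columns else None
        if len(self.re_idx) >= len(self.columns):
            raise ValueError("need q < p random effects")
        # z-scoring constants of the latent-dependent column (identity if raw)
        self.latent_scale = self.scaling.get(lc, (0.0, 1.0))

    @property
    def n_individuals(self) -> int:
        return len(self.seals)

    @property
    def p(self) -> int:
        return len(self.columns)

    @property
    def q(self) -> int:
        return len(self.re_idx)

    @property
    def n_obs(self) -> int:
        return int(sum(s.obs_mask.sum() for s in self.seals))

    @property
    def n_transitions(self) -> int:
        return int(sum(s.T for s in self.seals))

    def initial_latent(self) -> list:
        """Linear interpolation between the fixed endpoints (start state)."""
        return [np.linspace(s.L0, s.LT, s.T + 1) for s in self.seals]


def build_dataset(track_days: pd.DataFrame,
                  drift_summaries: pd.DataFrame,
                  physiology: Sequence[CapturePhysiology],
                  spec: Optional[ModelSpec] = None) -> SealDataset:
    """Assemble a :class:`SealDataset` from daily tables.

    The latent-dependent column's z-scoring constants are computed from
    the ratio of a linear lipid interpolation to R, so standardisation is
    fixed before sampling and independent of the latent draw.
    """
    spec = spec or ModelSpec()
    design, meta = build_design(track_days, drift_summaries, physiology, spec)
    phys = {p.individual_id: p for p in physiology}
    columns = meta["columns"]

    seals = []
    ll_vals = []
    for sid, g in drift_summaries.groupby("id", sort=True):
        g = g.sort_values("day_index")
        T = int(g["day_index"].max())
        p = phys[sid]
        R = non_lipid_series(spec.non_lipid_form, T, p.departure_nonlipid_kg,
                             p.arrival_nonlipid_kg, p.pup_birth_mass_kg)
        rows = design[design["id"] == sid].sort_values("day_index")
        if len(rows) != T:
            raise ValueError(f"{sid}: expected {T} design rows, got {len(rows)}")
        X = rows[columns].to_numpy(dtype=float)
        D = g["median_drift_rate"].to_numpy(dtype=float)
        h = g["n_drift_dives"].to_numpy()
        seals.append(SealArrays(sid, D, h, R, X,
                                p.departure_lipid_kg, p.arrival_lipid_kg))
        Linit = np.linspace(p.departure_lipid_kg, p.arrival_lipid_kg, T + 1)
        ll_vals.append(Linit[:-1] / R[:-1])

    scaling = dict(meta["scaling"])
    if spec.standardize and spec.latent_column in columns:
        v = np.concatenate(ll_vals)
        m, s = float(v.mean()), float(v.std())
        if s > 0:
            scaling[spec.latent_column] = (m, s)
    return SealDataset(seals=seals, columns=columns, spec=spec,
                       scaling=scaling, locations=meta["locations"])


def prepare(dives: pd.DataFrame,
            track: pd.DataFrame,
            captures: pd.DataFrame,
            states: Optional[pd.DataFrame] = None,
            spec: Optional[ModelSpec] = None,
            colony: Optional[tuple] = None,
            daily_loss_rate_kg: float = 0.0,
            phase_overrides: Optional[dict] = None) -> tuple:
    """Full preprocessing from raw CSV-shaped tables to a model-ready dataset.

    ``captures`` needs columns id, departure_date, departure_mass_kg,
    departure_lipid_pct, arrival_date, measured_mass_kg, days_since_birth,
    arrival_lipid_pct, location (and optionally pup_birth_mass_kg).
    ``colony`` (lon, lat) defaults to the first track position per
    individual.  Arrival mass is back-calculated with
    ``daily_loss_rate_kg`` (regression coefficient supplied via config).

    Returns ``(model_ready, dataset)``: the per-individual-day table and
    the assembled :class:`SealDataset`.
    """
    spec = spec or ModelSpec()
    cap = captures.set_index("id")
    departure = {i: pd.Timestamp(r["departure_date"]) for i, r in cap.iterrows()}
    n_days = {i: int((pd.Timestamp(r["arrival_date"]) - pd.Timestamp(r["departure_date"])).days)
              for i, r in cap.iterrows()}

    drift = median_daily_drift(dives, departure, n_days)
    daily = daily_positions(track, departure)

    parts = []
    for sid, g in daily.groupby("id", sort=True):
        g = g.sort_values("day_index").reset_index(drop=True)
        full = pd.DataFrame({"day_index": np.arange(n_days[sid] + 1)})
        g = full.merge(g.drop(columns="id"), on="day_index", how="left")
        g.insert(0, "id", sid)
        c_lon, c_lat = colony if colony is not None else (g["lon"].iloc[0], g["lat"].iloc[0])
        g["dist_colony_km"] = distance_to_colony(g["lon"], g["lat"], c_lon, c_lat)
        g["transit5d_km"] = running_transit(g["transit_km"].to_numpy())
        ov = phase_overrides.get(sid) if phase_overrides else None
        g["phase"] = segment_phases(g["dist_colony_km"].to_numpy(),
                                    g["transit5d_km"].to_numpy(),
                                    spec.foraging_threshold_km, overrides=ov)
        parts.append(g)
    track_days = pd.concat(parts, ignore_index=True)

    if states is not None:
        st = states.copy()
        st["_date"] = pd.to_datetime(st["date"]).dt.floor("D")
        st["day_index"] = st.apply(lambda r: (r["_date"] - departure[r["id"]]).days, axis=1)
        track_days = track_days.merge(st[["id", "day_index", "state_index"]],
                                      on=["id", "day_index"], how="left")

    physiology = []
    for sid, r in cap.iterrows():
        arrival = back_calculate_arrival_mass(r["measured_mass_kg"],
                                              r.get("days_since_birth", 0),
                                              daily_loss_rate_kg)
        physiology.append(CapturePhysiology(
            individual_id=sid,
            departure_mass_kg=r["departure_mass_kg"],
            departure_lipid_pct=r["departure_lipid_pct"],
            arrival_mass_kg=arrival,
            arrival_lipid_pct=r["arrival_lipid_pct"],
            foraging_location=r.get("location", ""),
            pup_birth_mass_kg=r.get("pup_birth_mass_kg", 0.0),
            days_between_arrival_and_weighing=int(r.get("days_since_birth", 0))))

    dataset = build_dataset(track_days, drift, physiology, spec)
    model_ready = track_days.merge(drift, on=["id", "day_index"], how="left")
    return model_ready, dataset
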