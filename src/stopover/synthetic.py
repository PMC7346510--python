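"""Synthetic telemetry streams and bird cohorts with known ground truth.

The generator emulates a quasi-experimental stopover study: cohorts of
two songbird species (common redstart CR, European robin ER) are
"captured" on a single day each, given morphometrics consistent with
the lean-body-mass calibrations, and assigned a behavioural outcome

* first-night departure ~ Bernoulli(logit^-1(a0 + a1 * z)), z the
  within-species z-score of the energy stores;
* proportion of night at take-off ~ Beta with logit mean
  b0 + b1*[robin] + b2*z and constant precision phi;
* departure bearing ~ von Mises per species.

Each departing bird then produces a multi-antenna detection stream: a
stationary ground phase (body/vegetation attenuation), a surge when the
bird becomes airborne at the true take-off, and a straight-line
constant-speed outbound track along the true bearing.  Received signal
is reference power - 20 log10(distance) + a cos^k antenna gain pattern
(floored), plus Gaussian noise, emitted only above the detection
threshold.

Randomness is keyed by a single integer seed; each bird draws from a
deterministic substream ``default_rng([seed, bird_index])`` so adding
birds never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import solar
from .energetics import LEAN_MASS_EQUATIONS, lean_body_mass

HELGOLAND_LAT = 54.183
HELGOLAND_LON = 7.883
#: Local civil time offset (h, CEST) used only to render capture clock times.
LOCAL_UTC_OFFSET_H = 2


@dataclass(frozen=True)
class SpeciesParams:
    """Morphometric, behavioural and directional parameters of one species."""

    wing_mean_mm: float
    wing_sd_mm: float
    muscle_probs: Dict[int, float]
    stores_range: Tuple[float, float] = (-0.05, 0.2)
    capture_date: date = date(2018, 9, 2)
    capture_window_h: Tuple[float, float] = (8.0, 13.0)  # local clock hours
    vm_mean_deg: float = 200.0
    vm_kappa: float = 5.0

    def validate(self, species: str) -> None:
        if self.stores_range[0] <= -1:
            raise ValueError("energy-store range lower bound must exceed -1")
        if self.vm_kappa < 0:
            raise ValueError("von Mises concentration must be >= 0")
        if abs(sum(self.muscle_probs.values()) - 1.0) > 1e-9:
            raise ValueError("muscle-score probabilities must sum to 1")
        for score in self.muscle_probs:
            if (species, score) not in LEAN_MASS_EQUATIONS:
                raise ValueError(
                    f"no lean-mass equation for ({species}, muscle score {score})"
                )


@dataclass(frozen=True)
class BehaviourParams:
    """Departure-decision model coefficients (logit scales)."""

    dep_intercept: float = -0.5    # first-night departure, logit
    dep_slope: float = 1.2         # per SD of energy stores
    beta_intercept: float = -1.20  # proportion-of-night linear predictor
    beta_species: float = 1.15     # robin offset
    beta_stores: float = -0.45     # per SD of energy stores
    beta_precision: float = 15.0   # beta-distribution precision phi
    stay_geom_p: float = 0.35      # extra stopover nights ~ geometric
    max_stopover_days: int = 17


@dataclass(frozen=True)
class SignalParams:
    """Radio-propagation and receiver parameters of the simulated array."""

    antenna_bearings: Tuple[float, ...] = tuple(range(0, 360, 30))
    gain_exponent: float = 4.0
    gain_floor_db: float = -30.0
    ref_power_db: float = 110.0
    noise_sd_db: float = 1.0
    threshold_db: float = 40.0
    sampling_interval_s: float = 5.0
    ground_speed_ms: float = 10.0
    ground_offset_m: float = 20.0
    ground_attenuation_db: float = 25.0
    pre_window_s: float = 1800.0
    max_airborne_s: float = 1200.0

    def validate(self) -> None:
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        if len(self.antenna_bearings) < 2:
            raise ValueError("need at least two antennas")


def _default_species() -> Dict[str, SpeciesParams]:
    return {
        "CR": SpeciesParams(
            wing_mean_mm=78.0,
            wing_sd_mm=2.0,
            muscle_probs={2: 1.0},
            capture_date=date(2018, 9, 2),
            capture_window_h=(8.0, 13.0),
            vm_mean_deg=232.0,
            vm_kappa=4.5,
        ),
        "ER": SpeciesParams(
            wing_mean_mm=73.0,
            wing_sd_mm=1.8,
            muscle_probs={2: 0.5, 3: 0.5},
            capture_date=date(2018, 10, 6),
            capture_window_h=(11.5, 15.0),
            vm_mean_deg=185.0,
            vm_kappa=15.0,
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    n_birds_per_species: Dict[str, int] = field(default_factory=lambda: {"CR": 14, "ER": 21})
    species_params: Dict[str, SpeciesParams] = field(default_factory=_default_species)
    behaviour: BehaviourParams = BehaviourParams()
    signal: SignalParams = SignalParams()
    site_lat: float = HELGOLAND_LAT
    site_lon: float = HELGOLAND_LON
    seed: int = 0

    def validate(self) -> None:
        for sp in self.n_birds_per_species:
            if sp not in self.species_params:
                raise ValueError(f"no species parameters for {sp!r}")
            self.species_params[sp].validate(sp)
        self.signal.validate()


def _bird_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def simulate_cohort(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a bird cohort and its ground truth.

    Returns ``(birds, truth)``: the bird table uses the capture-table
    column names (Time, Species, Muscle, Wing, Bodymass, take.off,
    dep.dir, days.on.island, dep.min.sunset, dep.realtive.night,
    wind.speed, wind.dir); the truth table carries the drawn energy
    stores, take-off instants, bearings and first-night flags.
    """
    config.validate()
    beh = config.behaviour
    rngs: List[np.random.Generator] = []
    draws = []
    idx = 0
    for species in sorted(config.n_birds_per_species):
        sp = config.species_params[species]
        for _ in range(config.n_birds_per_species[species]):
            rng = _bird_rng(config.seed, idx)
            wing = round(rng.normal(sp.wing_mean_mm, sp.wing_sd_mm) * 2) / 2
            scores = sorted(sp.muscle_probs)
            muscle = int(rng.choice(scores, p=[sp.muscle_probs[s] for s in scores]))
            lo, hi = sp.stores_range
            e = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            lean = lean_body_mass(species, muscle, wing)
            body = lean * (1.0 + e)
            cap_h = float(rng.uniform(*sp.capture_window_h))
            draws.append(
                dict(idx=idx, species=species, wing=wing, muscle=muscle, e=e,
                     lean=lean, body=body, cap_h=cap_h)
            )
            rngs.append(rng)
            idx += 1

    df = pd.DataFrame(draws)
    # Within-species z-score of the drawn stores drives behaviour.
    z = np.zeros(len(df))
    for species, grp in df.groupby("species"):
        sd = grp["e"].std(ddof=1)
        z[grp.index] = 0.0 if (not np.isfinite(sd) or sd == 0) else (grp["e"] - grp["e"].mean()) / sd
    df["z"] = z

    rows_bird, rows_truth = [], []
    for rec, rng in zip(df.itertuples(), rngs):
        sp = config.species_params[rec.species]
        p_dep = 1.0 / (1.0 + np.exp(-(beh.dep_intercept + beh.dep_slope * rec.z)))
        first_night = bool(rng.random() < p_dep)
        if first_night:
            nights = 1
        else:
            nights = min(2 + int(rng.geometric(beh.stay_geom_p)) - 1, beh.max_stopover_days)
        mu = 1.0 / (1.0 + np.exp(-(
            beh.beta_intercept
            + beh.beta_species * (rec.species == "ER")
            + beh.beta_stores * rec.z
        )))
        prop = float(rng.beta(mu * beh.beta_precision, (1.0 - mu) * beh.beta_precision))
        prop = min(max(prop, 1e-6), 1.0 - 1e-6)
        bearing = float(np.rad2deg(rng.vonmises(np.deg2rad(sp.vm_mean_deg), sp.vm_kappa)) % 360.0)

        night_date = sp.capture_date + timedelta(days=nights - 1)
        sunset, sunrise = solar.sun_events(night_date, config.site_lat, config.site_lon)
        night_len_min = (sunrise - sunset).total_seconds() / 60.0
        take_off = sunset + timedelta(minutes=prop * night_len_min)

        cap_hh = int(rec.cap_h)
        cap_mm = int(round((rec.cap_h - cap_hh) * 60)) % 60
        rows_bird.append(
            {
                "Time": f"{cap_hh:02d}:{cap_mm:02d}",
                "Species": rec.species,
                "Muscle": rec.muscle,
                "Wing": rec.wing,
                "Bodymass": rec.body,
                "take.off": take_off.isoformat(),
                "dep.dir": bearing,
                "days.on.island": nights,
                "dep.min.sunset": prop * night_len_min,
                "dep.realtive.night": prop,
                "wind.speed": 7.5 if rec.species == "CR" else 6.6,
                "wind.dir": 70.0 if rec.species == "CR" else 350.0,
            }
        )
        rows_truth.append(
            {
                "tag_id": f"tag{rec.idx:03d}",
                "species": rec.species,
                "energy_stores": rec.e,
                "stores_scaled": rec.z,
                "departed_first_night": first_night,
                "take_off_utc": pd.Timestamp(take_off),
                "bearing_deg": bearing,
                "days_on_island": nights,
            }
        )
    birds = pd.DataFrame(rows_bird)
    truth = pd.DataFrame(rows_truth)
    return birds, truth


def _gain_db(offset_deg: np.ndarray, params: SignalParams) -> np.ndarray:
    """cos^k boresight gain in dB, floored; zero on boresight."""
    off = np.deg2rad(np.abs((offset_deg + 180.0) % 360.0 - 180.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 10.0 * params.gain_exponent * np.log10(np.where(off < np.pi / 2, np.cos(off), 0.0))
    return np.maximum(np.nan_to_num(g, nan=-np.inf, neginf=-np.inf), params.gain_floor_db)


def simulate_detections(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Generate the multi-antenna detection stream implied by the truth.

    One row per received ping: ``ts`` (UTC), ``tag_id``, ``antenna_id``,
    ``sig_db``.  Birds whose ``take_off_utc`` is missing yield a
    stationary ground-phase stream only.
    """
    config.validate()
    sig = config.signal
    bearings = np.asarray(sig.antenna_bearings, dtype=float)
    rows = []
    for i, rec in enumerate(truth.itertuples()):
        rng = _bird_rng(config.seed + 1_000_000, i)
        t_off = rec.take_off_utc if pd.notna(getattr(rec, "take_off_utc", pd.NaT)) else None
        bearing = float(rec.bearing_deg) if t_off is not None else float(
            getattr(rec, "bearing_deg", 0.0) or 0.0
        )
        if t_off is None:
            anchor = pd.Timestamp("2018-09-02 20:00:00", tz="UTC")
        else:
            anchor = pd.Timestamp(t_off)
            if anchor.tzinfo is None:
                anchor = anchor.tz_localize("UTC")
        t0 = anchor.value / 1e9  # epoch seconds of true take-off
        n_pre = int(sig.pre_window_s // sig.sampling_interval_s)
        n_post = 0 if t_off is None else int(sig.max_airborne_s // sig.sampling_interval_s)
        # Tag bursts are not synchronized with the take-off: offset the
        # ping grid by a random phase within one sampling interval.
        phase = float(rng.uniform(0.0, sig.sampling_interval_s))
        times = t0 + phase + sig.sampling_interval_s * np.arange(-n_pre, n_post + 1)
        airborne = (times >= t0) & (t_off is not None)
        dist = np.where(
            airborne,
            sig.ground_offset_m + sig.ground_speed_ms * (times - t0),
            sig.ground_offset_m,
        )
        offsets = bearing - bearings[:, None]  # antennas x times
        gains = _gain_db(offsets, sig) * np.ones_like(times)
        power = (
            sig.ref_power_db
            - 20.0 * np.log10(dist)
            + gains
            - np.where(airborne, 0.0, sig.ground_attenuation_db)
        )
        noise = rng.normal(0.0, sig.noise_sd_db, size=power.shape)
        rx = power + noise
        ant_idx, t_idx = np.nonzero(rx >= sig.threshold_db)
        for a, k in zip(ant_idx, t_idx):
            rows.append(
                {
                    "ts": pd.Timestamp(times[k], unit="s", tz="UTC"),
                    "tag_id": getattr(rec, "tag_id", f"tag{i:03d}"),
                    "antenna_id": f"A{int(bearings[a]):03d}",
                    "sig_db": float(rx[a, k]),
                }
            )
    stream = pd.DataFrame(rows, columns=["ts", "tag_id", "antenna_id", "sig_db"])
    return stream.sort_values(["ts", "tag_id", "antenna_id"]).reset_index(drop=True)


def antenna_table(config: SimConfig) -> pd.DataFrame:
    """Antenna configuration table matching :func:`simulate_detections`."""
    return pd.DataFrame(
        {
            "antenna_id": [f"A{int(b):03d}" for b in config.signal.antenna_bearings],
            "site": "main",
            "bearing_deg": list(config.signal.antenna_bearings),
        }
    )
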