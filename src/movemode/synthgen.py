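"""Synthetic five-mode bivariate trip generator.

Every stage of the pipeline is testable without the original field
recordings by simulating labeled trips with the statistical structure
the classifiers exploit:

* speed (1 Hz) is a mean-reverting process around a mode-specific
  cruise level, interrupted by stop episodes (frequent for bus and
  car, rare for walk and rail), truncated at zero;
* acceleration magnitude (5 Hz) sits near gravity (9.81 m/s^2) with a
  mode-specific vibration: a dominant sinusoid (cadence for walk and
  bike, low-frequency sway for motorized modes) plus Gaussian noise,
  amplified while the speed is changing.

The default per-mode data volumes are proportional to 2.64 h of bike,
6.91 h of bus, 8.25 h of car, 7.30 h of rail and 21.62 h of walking,
scaled to two hours total so the full pipeline runs in minutes.  The
default profiles give the qualitative difficulty structure seen in
field data: walking and biking are easy to separate, while the three
motorized modes overlap in both speed and vibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import FA, MODES, Trip

#: Gravitational acceleration, m/s^2 — the resting accelerometer magnitude.
GRAVITY = 9.81

#: Per-mode recorded hours in the emulated study, used as volume ratios.
REFERENCE_HOURS = {"bike": 2.64, "bus": 6.91, "car": 8.25, "rail": 7.30, "walk": 21.62}


@dataclass(frozen=True)
class ModeProfile:
    """Kinematic and vibration signature of one transportation mode."""

    mode: str
    cruise_mph: float
    cruise_sd: float
    stops_per_min: float
    stop_dur_s: tuple[float, float]
    accel_base: float = GRAVITY
    vib_amp: float = 0.5
    vib_sd: float = 0.2
    vib_freq_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.vib_freq_hz >= FA / 2:
            raise ValueError(f"vibration frequency {self.vib_freq_hz} Hz is above Nyquist ({FA / 2} Hz)")


DEFAULT_PROFILES: dict[str, ModeProfile] = {
    # walk: slow, steady, strong step cadence near 2 Hz
    "walk": ModeProfile("walk", cruise_mph=3.0, cruise_sd=1.0, stops_per_min=0.1,
                        stop_dur_s=(5, 15), vib_amp=3.0, vib_sd=1.0, vib_freq_hz=2.0),
    # bike: moderate speed, pedaling cadence ~1.5 Hz, moderate vibration
    "bike": ModeProfile("bike", cruise_mph=10.0, cruise_sd=3.0, stops_per_min=0.3,
                        stop_dur_s=(10, 30), vib_amp=1.5, vib_sd=0.6, vib_freq_hz=1.5),
    # car: stop-and-go up to ~45 mph, low vibration
    "car": ModeProfile("car", cruise_mph=28.0, cruise_sd=9.0, stops_per_min=0.8,
                       stop_dur_s=(10, 45), vib_amp=0.35, vib_sd=0.25, vib_freq_hz=0.7),
    # bus: slower stop-and-go with periodic 20-40 s stops; road vibration
    # indistinguishable from car so speed pattern must separate them
    "bus": ModeProfile("bus", cruise_mph=17.0, cruise_sd=6.0, stops_per_min=1.2,
                       stop_dur_s=(20, 40), vib_amp=0.35, vib_sd=0.25, vib_freq_hz=0.6),
    # rail: fast, sustained, very smooth
    "rail": ModeProfile("rail", cruise_mph=40.0, cruise_sd=8.0, stops_per_min=0.15,
                        stop_dur_s=(30, 60), vib_amp=0.15, vib_sd=0.12, vib_freq_hz=0.3),
}


def identical_profiles(base: str = "bike") -> dict[str, ModeProfile]:
    """All five modes share one profile — the unseparable control case."""
    proto = DEFAULT_PROFILES[base]
    return {m: replace(proto, mode=m) for m in MODES}


@dataclass(frozen=True)
class SimConfig:
    """Volume and reproducibility settings for a simulated dataset."""

    total_hours: float = 2.0
    hours_by_mode: dict = field(default_factory=lambda: dict(REFERENCE_HOURS))
    target_trip_s: int = 600
    min_trip_s: int = 120
    seed: int = 0
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))

    def mode_seconds(self) -> dict[str, int]:
        """Per-mode seconds scaled so totals sum to ``total_hours``."""
        total_ref = sum(self.hours_by_mode.values())
        scale = self.total_hours / total_ref
        return {
            m: max(self.min_trip_s, int(round(self.hours_by_mode[m] * scale * 3600)))
            for m in MODES
        }


def simulate_trip(profile: ModeProfile, duration_s: int, seed: int, trip_id: str | None = None) -> Trip:
    """One synthetic single-mode trip; deterministic given the seed.

    Speed follows a discretized Ornstein-Uhlenbeck pull toward a target
    that is the cruise level while moving and zero during stop episodes
    (Poisson arrivals at the profile's stop rate).  Acceleration is the
    baseline magnitude plus a dominant-frequency sinusoid and white
    noise, with the sinusoid's amplitude boosted in proportion to the
    concurrent speed change.
    """
    if duration_s < 120:
        raise ValueError(f"trip duration must be >= 120 s, got {duration_s}")
    rng = np.random.default_rng(seed)

    # stop episodes
    stopped = np.zeros(duration_s, dtype=bool)
    t = 0.0
    rate = profile.stops_per_min / 60.0
    while rate > 0:
        t += rng.exponential(1.0 / rate)
        if t >= duration_s:
            break
        dur = rng.uniform(*profile.stop_dur_s)
        stopped[int(t) : min(duration_s, int(t + dur))] = True

    target = np.where(stopped, 0.0, profile.cruise_mph)
    theta, sigma = 0.15, profile.cruise_sd * 0.35
    speed = np.empty(duration_s)
    speed[0] = max(0.0, profile.cruise_mph + rng.normal(0, profile.cruise_sd))
    for i in range(1, duration_s):
        drift = theta * (target[i] - speed[i - 1])
        speed[i] = speed[i - 1] + drift + sigma * rng.normal()
    speed = np.maximum(speed, 0.0)

    # 5 Hz acceleration magnitude
    n_acc = duration_s * FA
    tt = np.arange(n_acc) / FA
    phase = rng.uniform(0, 2 * np.pi)
    dspeed = np.abs(np.gradient(speed))
    boost = 1.0 + 0.8 * np.repeat(dspeed, FA) / max(profile.cruise_sd, 0.5)
    vib = profile.vib_amp * boost * np.sin(2 * np.pi * profile.vib_freq_hz * tt + phase)
    accel = profile.accel_base + vib + rng.normal(0, profile.vib_sd, n_acc)
    accel = np.maximum(accel, 1e-3)

    return Trip(
        trip_id=trip_id or f"{profile.mode}_{seed}",
        mode=profile.mode,
        speed=speed,
        accel=accel,
    )


def simulate_dataset(config: SimConfig = SimConfig()) -> tuple[list[Trip], dict]:
    """Labeled trips for all five modes plus a ground-truth manifest.

    Each mode's configured seconds are divided into roughly equal trips
    near ``target_trip_s`` long (never below ``min_trip_s``); per-mode
    totals equal the configured seconds exactly.  Rebuilding with the
    manifest's seed reproduces the dataset.
    """
    rng = np.random.default_rng(config.seed)
    trips: list[Trip] = []
    seconds = config.mode_seconds()
    for mode in MODES:
        total = seconds[mode]
        n_trips = max(1, int(round(total / config.target_trip_s)))
        base = total // n_trips
        durations = [base + (1 if k < total - base * n_trips else 0) for k in range(n_trips)]
        durations = [max(config.min_trip_s, d) for d in durations]
        for k, dur in enumerate(durations):
            trip_seed = int(rng.integers(0, 2**31 - 1))
            trips.append(
                simulate_trip(config.profiles[mode], dur, trip_seed, trip_id=f"{mode}{k:02d}")
            )
    manifest = {
        "seed": config.seed,
        "total_hours": config.total_hours,
        "mode_seconds": seconds,
        "n_trips": len(trips),
        "profiles": {m: vars(p) for m, p in config.profiles.items()},
    }
    return trips, manifest


# ---------------------------------------------------------------------------
# Raw-file emission: the same three delimited files the preprocessor reads


def emit_raw_files(trips: list[Trip], directory, seed: int = 0, gap_s: int = 60) -> dict:
    """Write accelerometer/speed/annotation CSVs for a trip collection.

    Trips are laid end to end on a global clock with ``gap_s`` quiet
    seconds between them.  The scalar acceleration magnitude is split
    onto three axes via a slowly rotating random orientation so the
    accelerometer file is tri-axial like a real recording; speed is
    written directly (``t, speed_mph``).  Returns the file paths.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    acc_rows, spd_rows, ann_rows = [], [], []
    t0 = 0
    for tr in trips:
        n_acc = len(tr.accel)
        # slowly rotating unit orientation
        walk = rng.normal(0, 0.01, (n_acc, 3)).cumsum(axis=0) + rng.normal(0, 1, 3)
        walk /= np.linalg.norm(walk, axis=1, keepdims=True)
        xyz = walk * tr.accel[:, None]
        t_acc = t0 + np.arange(n_acc) / FA
        acc_rows.append(pd.DataFrame({"t": t_acc, "ax": xyz[:, 0], "ay": xyz[:, 1], "az": xyz[:, 2]}))
        spd_rows.append(pd.DataFrame({"t": t0 + np.arange(tr.duration_s, dtype=float), "speed_mph": tr.speed}))
        ann_rows.append({"trip_id": tr.trip_id, "start": t0, "end": t0 + tr.duration_s, "mode": tr.mode})
        t0 += tr.duration_s + gap_s

    paths = {
        "accel": directory / "accelerometer.csv",
        "gps": directory / "speed.csv",
        "annotations": directory / "annotations.csv",
    }
    pd.concat(acc_rows, ignore_index=True).to_csv(paths["accel"], index=False)
    pd.concat(spd_rows, ignore_index=True).to_csv(paths["gps"], index=False)
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], index=False)
    return {k: str(v) for k, v in paths.items()}
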