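"""Raw sensor records -> clean, labeled, single-mode trips.

The raw inputs are three delimited text streams: tri-axial accelerometer
records at ~5 Hz, GPS fixes (or precomputed speed) at ~1 Hz, and trip
annotations giving start/end times and the true mode.  This module

* collapses tri-axial acceleration to its orientation-free magnitude,
* converts consecutive GPS fixes to speed in mph (haversine distance),
* snaps jittery streams onto the nominal 1 Hz / 5 Hz grids,
* removes all data within 10 s of a mode change,
* drops trips with fewer than 120 s of data, and
* partitions units 60/20/20 into train/validation/test by simple random
  sampling.

Seconds in which the GPS fix is missing, or in which fewer than half of
the expected accelerometer samples arrived, are treated as missing; a
trip is split at missing seconds so that no downstream window ever spans
one.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core import FA, MIN_TRIP_S, MODES, MPS_PER_MPH, SplitAssignment, Trip

logger = logging.getLogger(__name__)

#: Mean Earth radius, metres (spherical model).
EARTH_RADIUS_M = 6_371_000.0

#: Seconds removed on either side of a mode change.
TRANSITION_MARGIN_S = 10


def accel_magnitude(ax, ay, az):
    """Euclidean norm of the acceleration vector, m/s^2.

    Phone orientation is uncontrolled in real-world carrying positions,
    so the individual axes are uninterpretable; the magnitude is
    invariant to device rotation and is used as the sole accelerometer
    channel.  Accepts scalars or arrays.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    out = np.sqrt(ax * ax + ay * ay + az * az)
    return float(out) if out.ndim == 0 else out


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance between two points in metres."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def speed_from_coordinates(fix_prev, fix_next, dt):
    """Speed in mph implied by two GPS fixes ``dt`` seconds apart.

    Parameters
    ----------
    fix_prev, fix_next
        ``(lat, lon)`` pairs in decimal degrees.
    dt
        Elapsed seconds, strictly positive.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    d = haversine_m(fix_prev[0], fix_prev[1], fix_next[0], fix_next[1])
    return (d / dt) / MPS_PER_MPH


def trim_transitions(stream: pd.DataFrame, margin_s: float = TRANSITION_MARGIN_S) -> pd.DataFrame:
    """Remove samples within ``margin_s`` seconds of any mode change.

    ``stream`` must have columns ``t`` (seconds) and ``mode``; rows must
    be time-sorted.  A mode change happens at the first timestamp of the
    new mode; a label transition across a time gap longer than the
    margin is a recording break, not a change, which makes the operation
    idempotent.  Samples with ``|t - t_change| <= margin_s`` for *any*
    change are dropped; overlapping margins are unioned.
    """
    if stream.empty:
        return stream.copy()
    t = stream["t"].to_numpy(dtype=float)
    modes = stream["mode"].to_numpy()
    adjacent = np.diff(t) <= max(margin_s, 1.0)
    changes = t[1:][(modes[1:] != modes[:-1]) & adjacent]
    if changes.size == 0:
        return stream.copy()
    keep = np.ones(len(stream), dtype=bool)
    for tc in changes:
        keep &= np.abs(t - tc) > margin_s
    return stream.loc[keep].copy()


def filter_short_trips(trips: list[Trip], min_s: int = MIN_TRIP_S) -> list[Trip]:
    """Keep only trips with at least ``min_s`` seconds of data, in order."""
    return [tr for tr in trips if tr.duration_s >= min_s]


def split_dataset(unit_ids, seed: int, proportions=(0.6, 0.2, 0.2)) -> SplitAssignment:
    """Randomly partition units into train/validation/test.

    Same seed, same units -> identical assignment.  Sizes match the
    proportions up to rounding (cumulative-boundary rounding, so the
    partition is always exhaustive).
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {proportions}")
    unit_ids = list(unit_ids)
    n = len(unit_ids)
    if n < 3:
        raise ValueError("need at least 3 units to form a 3-way split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    b1 = int(round(proportions[0] * n))
    b2 = int(round((proportions[0] + proportions[1]) * n))
    assignment = {}
    for rank, idx in enumerate(order):
        part = "train" if rank < b1 else ("validation" if rank < b2 else "test")
        assignment[unit_ids[idx]] = part
    return SplitAssignment(assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# Raw-file ingestion


def load_raw(accel_path, gps_path, annotations_path):
    """Read the three delimited input files into DataFrames.

    * accelerometer: columns ``t, ax, ay, az``
    * GPS: columns ``t, lat, lon`` or precomputed ``t, speed_mph``
    * annotations: columns ``trip_id, start, end, mode``

    Non-finite accelerometer records are rejected with a warning.
    """
    accel = pd.read_csv(accel_path)
    gps = pd.read_csv(gps_path)
    ann = pd.read_csv(annotations_path)
    bad = ~np.isfinite(accel[["ax", "ay", "az"]].to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} non-finite accelerometer records")
        accel = accel.loc[~bad]
    for df, name in ((accel, "accelerometer"), (gps, "gps")):
        if not df["t"].is_monotonic_increasing:
            raise ValueError(f"{name} timestamps must be increasing")
    bad_modes = set(ann["mode"]) - set(MODES)
    if bad_modes:
        raise ValueError(f"unknown modes in annotations: {sorted(bad_modes)}")
    if (ann["end"] <= ann["start"]).any():
        raise ValueError("annotation intervals must have positive length")
    return accel, gps, ann


def _speed_series(gps: pd.DataFrame) -> pd.DataFrame:
    """Per-fix speed in mph, either passed through or derived from fixes."""
    if "speed_mph" in gps.columns:
        return gps[["t", "speed_mph"]].copy()
    t = gps["t"].to_numpy(dtype=float)
    lat = gps["lat"].to_numpy(dtype=float)
    lon = gps["lon"].to_numpy(dtype=float)
    dt = np.diff(t)
    d = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    sp = np.full(len(t), np.nan)
    sp[1:] = np.where(dt > 0, (d / np.where(dt > 0, dt, 1.0)) / MPS_PER_MPH, np.nan)
    if len(sp) > 1:
        sp[0] = sp[1]
    return pd.DataFrame({"t": t, "speed_mph": sp})


def _snap_second_grid(seconds, times, values):
    """Nearest-sample snap of (times, values) onto integer ``seconds``.

    Returns the snapped values and a missing mask (no sample within
    half a grid step of that second).
    """
    out = np.full(len(seconds), np.nan)
    if len(times) == 0:
        return out, np.ones(len(seconds), dtype=bool)
    idx = np.searchsorted(times, seconds)
    idx = np.clip(idx, 0, len(times) - 1)
    left = np.clip(idx - 1, 0, len(times) - 1)
    pick = np.where(np.abs(times[left] - seconds) <= np.abs(times[idx] - seconds), left, idx)
    dist = np.abs(times[pick] - seconds)
    ok = dist <= 0.5
    out[ok] = values[pick[ok]]
    return out, ~ok


def build_trips(
    accel: pd.DataFrame,
    gps: pd.DataFrame,
    annotations: pd.DataFrame,
    margin_s: float = TRANSITION_MARGIN_S,
    min_s: int = MIN_TRIP_S,
) -> list[Trip]:
    """Assemble labeled single-mode trips from raw streams.

    Each annotation interval ``[start, end)`` is resampled onto the
    nominal grids: one speed value per second (nearest fix) and five
    acceleration magnitudes per second (nearest sample per 0.2 s slot;
    a second with fewer than three of its five slots filled counts as
    missing).  Seconds within ``margin_s`` of a mode change — two
    annotations abutting with different modes — are removed, trips are
    split at missing seconds, and segments shorter than ``min_s`` are
    dropped.
    """
    speed_df = _speed_series(gps)
    sp_t = speed_df["t"].to_numpy(dtype=float)
    sp_v = speed_df["speed_mph"].to_numpy(dtype=float)
    ac_t = accel["t"].to_numpy(dtype=float)
    ac_v = accel_magnitude(
        accel["ax"].to_numpy(dtype=float),
        accel["ay"].to_numpy(dtype=float),
        accel["az"].to_numpy(dtype=float),
    )

    ann = annotations.sort_values("start").reset_index(drop=True)
    # Mode-change times: the start of an annotation that directly follows
    # (within one sample) an annotation of a different mode.
    change_times = []
    for i in range(1, len(ann)):
        if ann.loc[i, "start"] - ann.loc[i - 1, "end"] <= 1.0 and ann.loc[i, "mode"] != ann.loc[i - 1, "mode"]:
            change_times.append(float(ann.loc[i, "start"]))

    trips: list[Trip] = []
    for _, row in ann.iterrows():
        start, end = int(np.ceil(row["start"])), int(np.floor(row["end"]))
        seconds = np.arange(start, end, dtype=float)
        if seconds.size == 0:
            continue
        spd, sp_missing = _snap_second_grid(seconds, sp_t, sp_v)
        sp_missing |= ~np.isfinite(spd)

        # 5 Hz grid: one slot per 0.2 s within each second.
        sub = (seconds[:, None] + np.arange(FA)[None, :] / FA).ravel()
        acc, ac_missing_slot = _snap_second_grid_fine(sub, ac_t, ac_v)
        slot_missing = ac_missing_slot.reshape(-1, FA)
        ac_second_missing = slot_missing.sum(axis=1) >= 3
        # Fill isolated missing slots within a kept second by interpolation.
        acc = _fill_slots(acc)

        keep = ~(sp_missing | ac_second_missing)
        for tc in change_times:
            keep &= np.abs(seconds - tc) > margin_s

        for seg_start, seg_stop in _runs(keep):
            n = seg_stop - seg_start
            if n < min_s:
                continue
            trips.append(
                Trip(
                    trip_id=f"{row['trip_id']}_{int(seconds[seg_start])}",
                    mode=row["mode"],
                    speed=np.maximum(spd[seg_start:seg_stop], 0.0),
                    accel=np.maximum(acc[seg_start * FA : seg_stop * FA], 0.0),
                )
            )
    if not trips:
        logger.warning("no trips of at least %d s survived preprocessing", min_s)
    return trips


def _snap_second_grid_fine(grid, times, values):
    """Nearest-sample snap onto an arbitrary grid with 0.2 s slots."""
    out = np.full(len(grid), np.nan)
    if len(times) == 0:
        return out, np.ones(len(grid), dtype=bool)
    idx = np.searchsorted(times, grid)
    idx = np.clip(idx, 0, len(times) - 1)
    left = np.clip(idx - 1, 0, len(times) - 1)
    pick = np.where(np.abs(times[left] - grid) <= np.abs(times[idx] - grid), left, idx)
    ok = np.abs(times[pick] - grid) <= 0.5 / FA
    out[ok] = values[pick[ok]]
    return out, ~ok


def _fill_slots(values):
    """Linearly interpolate isolated NaN slots in a 5 Hz series."""
    out = values.copy()
    nans = ~np.isfinite(out)
    if nans.any() and (~nans).any():
        idx = np.arange(len(out))
        out[nans] = np.interp(idx[nans], idx[~nans], out[~nans])
    return out


def _runs(mask):
    """Yield (start, stop) index pairs of consecutive True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    """Flatten trips into one row per second (speed + five accel samples)."""
    rows = []
    for tr in trips:
        acc = tr.accel.reshape(-1, FA)
        for sec in range(tr.duration_s):
            rows.append(
                {
                    "trip_id": tr.trip_id,
                    "mode": tr.mode,
                    "second": sec,
                    "speed_mph": tr.speed[sec],
                    **{f"a{k}": acc[sec, k] for k in range(FA)},
                }
            )
    return pd.DataFrame(rows)


def frame_to_trips(frame: pd.DataFrame) -> list[Trip]:
    """Inverse of :func:`trips_to_frame`."""
    trips = []
    for trip_id, grp in frame.groupby("trip_id", sort=False):
        grp = grp.sort_values("second")
        trips.append(
            Trip(
                trip_id=str(trip_id),
                mode=grp["mode"].iloc[0],
                speed=grp["speed_mph"].to_numpy(dtype=float),
                accel=grp[[f"a{k}" for k in range(FA)]].to_numpy(dtype=float).ravel(),
            )
        )
    return trips
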