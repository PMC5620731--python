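"""Windowed summary features of the bivariate sensor stream.

For every window end time t (on a 5 s grid, at least 120 s into the
trip) and every window length H in {30, 60, 90, 120} s, eight order and
moment statistics — mean, median, variance, minimum, maximum,
interquartile range, 20th and 80th percentiles — are computed on four
stochastic processes: speed S, acceleration magnitude A, and their
iterated differences dS and dA (successive differences, newer minus
older).  That is 8 x 4 x 4 = 128 features.  The acceleration window
additionally contributes, per window length, its lag-1 autocorrelation
and the sums of the first six real and first six imaginary components
of its discrete Fourier transform (DC excluded): 3 x 4 = 12 more, for a
total of 140 features per row.

Column names are systematic: ``{process}_{stat}_{H}`` for the 128 base
features (e.g. ``S_mean_30``, ``dA_p80_120``) and ``A_autocorr_{H}``,
``A_fourier_re_{H}``, ``A_fourier_im_{H}`` for the extras.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FA, Trip

STATS = ("mean", "median", "var", "min", "max", "iqr", "p20", "p80")
PROCESSES = ("S", "A", "dS", "dA")
EXTRAS = ("autocorr", "fourier_re", "fourier_im")


@dataclass(frozen=True)
class WindowSpec:
    """Window lengths, step, and the minimum history a row requires."""

    windows: tuple[int, ...] = (30, 60, 90, 120)
    step: int = 5

    def __post_init__(self) -> None:
        if tuple(sorted(self.windows)) != tuple(self.windows):
            raise ValueError("windows must be sorted ascending")
        if any(w % self.step for w in self.windows):
            raise ValueError("step must divide every window length")

    @property
    def min_history(self) -> int:
        return max(self.windows)


def feature_columns(spec: WindowSpec = WindowSpec()) -> list[str]:
    """The 140 feature names in deterministic order."""
    cols = [f"{p}_{s}_{H}" for p in PROCESSES for H in spec.windows for s in STATS]
    cols += [f"A_{e}_{H}" for e in EXTRAS for H in spec.windows]
    return cols


def iterated_differences(series) -> np.ndarray:
    """Successive differences of a most-recent-first series.

    ``out[i] = series[i] - series[i+1]``, i.e. newer minus older; the
    result has length ``len(series) - 1`` and telescopes to
    ``series[0] - series[-1]``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to difference")
    return x[:-1] - x[1:]


def window_stats(values) -> dict:
    """The eight window statistics of a sample.

    Variance is the sample variance (n-1 denominator); percentiles use
    linear interpolation between order statistics, and the
    interquartile range is p75 - p25.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    p20, p25, p75, p80 = np.percentile(x, [20, 25, 75, 80])
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "var": float(np.var(x, ddof=1)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "iqr": float(p75 - p25),
        "p20": float(p20),
        "p80": float(p80),
    }


def accel_extras(window) -> tuple[float, float, float]:
    """Lag-1 autocorrelation and truncated Fourier sums of a window.

    Returns ``(autocorr, fourier_re, fourier_im)`` where the Fourier
    sums run over components 1..6 of the unnormalized DFT (the DC term,
    which duplicates the mean feature, is excluded).  A zero-variance
    window has autocorrelation reported as 0.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 12:
        raise ValueError("window too short for Fourier extras (need >= 12 samples)")
    a, b = x[:-1], x[1:]
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        ac = 0.0
    else:
        ac = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    F = np.fft.fft(x)[1:7]
    return ac, float(np.sum(F.real)), float(np.sum(F.imag))


# ---------------------------------------------------------------------------
# Vectorized internals: stats over the rows of a 2-D window matrix.


def _stats_matrix(W: np.ndarray) -> dict:
    p20, p25, p75, p80 = np.percentile(W, [20, 25, 75, 80], axis=1)
    return {
        "mean": W.mean(axis=1),
        "median": np.median(W, axis=1),
        "var": W.var(axis=1, ddof=1),
        "min": W.min(axis=1),
        "max": W.max(axis=1),
        "iqr": p75 - p25,
        "p20": p20,
        "p80": p80,
    }


def _extras_matrix(W: np.ndarray) -> dict:
    a, b = W[:, :-1], W[:, 1:]
    sa, sb = a.std(axis=1), b.std(axis=1)
    cov = ((a - a.mean(axis=1, keepdims=True)) * (b - b.mean(axis=1, keepdims=True))).mean(axis=1)
    denom = sa * sb
    ac = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    F = np.fft.fft(W, axis=1)[:, 1:7]
    return {"autocorr": ac, "fourier_re": F.real.sum(axis=1), "fourier_im": F.imag.sum(axis=1)}


def _trip_rows(trip: Trip, spec: WindowSpec) -> pd.DataFrame | None:
    T = trip.duration_s
    t_grid = np.arange(spec.min_history, T + 1, spec.step)
    if t_grid.size == 0:
        return None
    cols: dict = {}
    for H in spec.windows:
        # window of seconds [t-H, t): speed indices t-H..t-1, accel 5(t-H)..5t-1
        S = np.stack([trip.speed[t - H : t] for t in t_grid])
        A = np.stack([trip.accel[(t - H) * FA : t * FA] for t in t_grid])
        # iterated differences (newer minus older) within each window
        dS = S[:, 1:] - S[:, :-1]
        dA = A[:, 1:] - A[:, :-1]
        for proc, W in (("S", S), ("A", A), ("dS", dS), ("dA", dA)):
            for stat, vals in _stats_matrix(W).items():
                cols[f"{proc}_{stat}_{H}"] = vals
        for extra, vals in _extras_matrix(A).items():
            cols[f"A_{extra}_{H}"] = vals
    df = pd.DataFrame(cols)
    df.insert(0, "trip_id", trip.trip_id)
    df.insert(1, "t", t_grid)
    df.insert(2, "mode", trip.mode)
    return df


def build_feature_table(trips: list[Trip], spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """One row of 140 features per (trip, window-end time).

    Rows are emitted at ``t = min_history, min_history + step, ...`` up
    to the trip duration, so every row has full history for all four
    window lengths; trips shorter than the largest window contribute no
    rows.  Columns are ``trip_id, t, mode`` followed by the names from
    :func:`feature_columns` in deterministic order.
    """
    frames = [f for trip in trips if (f := _trip_rows(trip, spec)) is not None]
    order = ["trip_id", "t", "mode"] + feature_columns(spec)
    if not frames:
        return pd.DataFrame(columns=order)
    table = pd.concat(frames, ignore_index=True)
    return table[order]
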