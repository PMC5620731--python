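"""Bivariate movelet dictionaries.

A *movelet* is a fixed-duration window cut jointly from the two sensor
channels of a trip: H seconds of speed (H points at 1 Hz) paired with
the same H seconds of acceleration magnitude (5H points at 5 Hz).  All
movelets of one mode form that mode's *chapter*; the union of chapters
is the dictionary.  Classification of a new window is nearest-chapter
search under a frequency-scaled distance

    d(X, Y) = ||A_X - A_Y||_2 / fA  +  ||S_X - S_Y||_2 / fS

which equalizes the contribution of the two channels despite their
different sampling rates.  Channels are first scaled to [0, 1] using the
training data's global minima and maxima so that neither channel's raw
range dominates the distance.

The dictionary is refined against a validation set: every validation
movelet is matched to its nearest training movelet; a training movelet
matched by more than one mode is *ambiguous* and removed; within each
chapter only the most-matched movelets are kept, down to a configurable
fraction of the chapter's size at formation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .core import FA, FS, MODES, Trip

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MoveletConfig:
    """Window geometry for movelet generation and matching.

    H is the window length in seconds (30, 60, 90 or 120 in the standard
    sweep); delta is the slide between consecutive windows.  Small delta
    relative to H induces heavy overlap: each interior second belongs to
    H/delta movelets.
    """

    H: int = 30
    delta: int = 5
    fs: int = FS
    fa: int = FA

    def __post_init__(self) -> None:
        if self.delta < 1 or self.H < self.delta:
            raise ValueError(f"need H >= delta >= 1, got H={self.H}, delta={self.delta}")
        if self.H % self.delta != 0:
            raise ValueError(f"H={self.H} must be a multiple of delta={self.delta}")


@dataclass
class Movelet:
    """One window pair with its provenance."""

    speed: np.ndarray  # H * fs values
    accel: np.ndarray  # H * fa values
    mode: str
    trip_id: str
    end_t: int  # window end, seconds from trip start

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)


def generate_chapter(trip: Trip, config: MoveletConfig) -> list[Movelet]:
    """All movelets of a trip on the sliding grid.

    Windows start at 0, delta, 2*delta, ... while the window still fits:
    the count for a trip of duration T >= H is floor((T - H)/delta) + 1.
    A trip shorter than H yields no movelets.
    """
    T = trip.duration_s
    if T < config.H:
        logger.info("trip %s shorter than H=%d; no movelets", trip.trip_id, config.H)
        return []
    out = []
    i = 0
    while config.delta * i + config.H <= T:
        s0 = config.delta * i
        s1 = s0 + config.H
        out.append(
            Movelet(
                speed=trip.speed[s0 * config.fs : s1 * config.fs],
                accel=trip.accel[s0 * config.fa : s1 * config.fa],
                mode=trip.mode,
                trip_id=trip.trip_id,
                end_t=s1,
            )
        )
        i += 1
    return out


def generate_movelets(trips: list[Trip], config: MoveletConfig) -> list[Movelet]:
    """Concatenation of every trip's chapter, trip order preserved."""
    out: list[Movelet] = []
    for trip in trips:
        out.extend(generate_chapter(trip, config))
    return out


@dataclass
class ChannelScaler:
    """Global per-channel [0, 1] scaling learned from training movelets.

    The scaling is global (one min/max per channel over all training
    movelets), not per-window: per-window scaling would erase the
    absolute speed level, which is exactly what separates modes.  Data
    outside the training range are clipped into [0, 1].
    """

    speed_min: float = 0.0
    speed_max: float = 1.0
    accel_min: float = 0.0
    accel_max: float = 1.0

    @classmethod
    def fit(cls, movelets: list[Movelet]) -> "ChannelScaler":
        if not movelets:
            raise ValueError("cannot fit scaler on empty training set")
        sp = np.concatenate([m.speed for m in movelets])
        ac = np.concatenate([m.accel for m in movelets])
        sc = cls(float(sp.min()), float(sp.max()), float(ac.min()), float(ac.max()))
        if sc.speed_max <= sc.speed_min:
            raise ValueError("speed channel is constant in training data; cannot scale")
        if sc.accel_max <= sc.accel_min:
            raise ValueError("accel channel is constant in training data; cannot scale")
        return sc

    def transform(self, movelet: Movelet) -> Movelet:
        sp = np.clip((movelet.speed - self.speed_min) / (self.speed_max - self.speed_min), 0.0, 1.0)
        ac = np.clip((movelet.accel - self.accel_min) / (self.accel_max - self.accel_min), 0.0, 1.0)
        return Movelet(sp, ac, movelet.mode, movelet.trip_id, movelet.end_t)

    def transform_all(self, movelets: list[Movelet]) -> list[Movelet]:
        return [self.transform(m) for m in movelets]


def movelet_distance(x: Movelet, y: Movelet, config: MoveletConfig) -> float:
    """Frequency-scaled bivariate distance between two (scaled) movelets."""
    if len(x.speed) != len(y.speed) or len(x.accel) != len(y.accel):
        raise ValueError("movelets have mismatched window lengths (different H?)")
    da = float(np.linalg.norm(x.accel - y.accel)) / config.fa
    ds = float(np.linalg.norm(x.speed - y.speed)) / config.fs
    return da + ds


def _stack(movelets: list[Movelet]):
    sp = np.stack([m.speed for m in movelets])
    ac = np.stack([m.accel for m in movelets])
    return sp, ac


def _distance_matrix(a: list[Movelet], b: list[Movelet], config: MoveletConfig) -> np.ndarray:
    """Pairwise frequency-scaled distances, shape (len(a), len(b))."""
    sp_a, ac_a = _stack(a)
    sp_b, ac_b = _stack(b)
    return cdist(ac_a, ac_b) / config.fa + cdist(sp_a, sp_b) / config.fs


def match_validation(
    training: list[Movelet], validation: list[Movelet], config: MoveletConfig
) -> np.ndarray:
    """Match each validation movelet to its nearest training movelet.

    Returns an integer table of shape (len(training), len(MODES)):
    entry (i, m) counts validation movelets of mode m whose nearest
    training movelet is i.  Column order follows :data:`MODES`.  Ties in
    distance go to the earlier training movelet (argmin convention).
    """
    if not training:
        raise ValueError("empty training set")
    counts = np.zeros((len(training), len(MODES)), dtype=int)
    if not validation:
        return counts
    d = _distance_matrix(validation, training, config)
    nearest = np.argmin(d, axis=1)
    mode_idx = {m: k for k, m in enumerate(MODES)}
    for v, tr_i in enumerate(nearest):
        counts[tr_i, mode_idx[validation[v].mode]] += 1
    return counts


@dataclass
class MoveletDictionary:
    """Refined per-mode chapters plus the scaler that normalizes queries."""

    chapters: dict = field(default_factory=dict)  # mode -> list[Movelet]
    counts: dict = field(default_factory=dict)  # mode -> np.ndarray of match counts
    scaler: ChannelScaler | None = None
    config: MoveletConfig = field(default_factory=MoveletConfig)
    keep_fraction: float = 0.5

    def n_movelets(self) -> int:
        return sum(len(ch) for ch in self.chapters.values())

    # -- persistence (plain text) -------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "H": self.config.H,
            "delta": self.config.delta,
            "keep_fraction": self.keep_fraction,
            "scaler": vars(self.scaler) if self.scaler else None,
            "modes": list(self.chapters),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for mode, chapter in self.chapters.items():
            import pandas as pd

            H = self.config.H
            rows = []
            for m, c in zip(chapter, self.counts[mode]):
                rows.append(
                    {
                        "trip_id": m.trip_id,
                        "end_t": m.end_t,
                        "count": int(c),
                        **{f"s{k}": m.speed[k] for k in range(H * self.config.fs)},
                        **{f"a{k}": m.accel[k] for k in range(H * self.config.fa)},
                    }
                )
            pd.DataFrame(rows).to_csv(directory / f"chapter_{mode}.csv", index=False)

    @classmethod
    def load(cls, directory) -> "MoveletDictionary":
        import pandas as pd

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = MoveletConfig(H=manifest["H"], delta=manifest["delta"])
        scaler = ChannelScaler(**manifest["scaler"]) if manifest["scaler"] else None
        chapters: dict = {}
        counts: dict = {}
        for mode in manifest["modes"]:
            df = pd.read_csv(directory / f"chapter_{mode}.csv")
            sp_cols = [f"s{k}" for k in range(config.H * config.fs)]
            ac_cols = [f"a{k}" for k in range(config.H * config.fa)]
            chapters[mode] = [
                Movelet(
                    speed=row[sp_cols].to_numpy(dtype=float),
                    accel=row[ac_cols].to_numpy(dtype=float),
                    mode=mode,
                    trip_id=str(row["trip_id"]),
                    end_t=int(row["end_t"]),
                )
                for _, row in df.iterrows()
            ]
            counts[mode] = df["count"].to_numpy(dtype=int)
        return cls(
            chapters=chapters,
            counts=counts,
            scaler=scaler,
            config=config,
            keep_fraction=manifest["keep_fraction"],
        )


def refine_dictionary(
    training: list[Movelet],
    match_counts: np.ndarray,
    config: MoveletConfig,
    keep_fraction: float = 0.5,
) -> MoveletDictionary:
    """Build refined chapters from the validation match counts.

    For each mode m the chapter is formed from every training movelet
    matched by at least one validation movelet of mode m; the chapter
    size at formation (kappa_m) is frozen.  Ambiguous movelets — those
    matched by more than one mode — are then removed from every chapter,
    and finally the least-matched movelets are dropped while the chapter
    holds more than ``keep_fraction * kappa_m`` movelets.  Ties in match
    count are broken by dropping the later (trip_id, end_t) first.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    matched_modes = match_counts > 0
    n_modes_matched = matched_modes.sum(axis=1)

    chapters: dict = {}
    counts_out: dict = {}
    empty_modes = []
    for mi, mode in enumerate(MODES):
        members = np.flatnonzero(matched_modes[:, mi])
        kappa = len(members)  # frozen at formation, before ambiguity removal
        members = members[n_modes_matched[members] == 1]  # drop ambiguous
        cnts = match_counts[members, mi]
        # drop least-matched until within keep_fraction * kappa; stable
        # order: by count desc, then source order (earlier kept first)
        order = np.lexsort((members, -cnts))
        limit = keep_fraction * kappa
        k = len(order)
        while k > limit:
            k -= 1
        keep = np.sort(members[order[:k]])
        if keep.size == 0:
            empty_modes.append(mode)
            chapters[mode] = []
            counts_out[mode] = np.zeros(0, dtype=int)
            continue
        chapters[mode] = [training[i] for i in keep]
        counts_out[mode] = match_counts[keep, mi]
    if len(empty_modes) == len(MODES):
        raise ValueError(f"refinement left every chapter empty: {empty_modes}")
    if empty_modes:
        logger.warning("empty refined chapters for modes: %s", empty_modes)
    return MoveletDictionary(
        chapters=chapters, counts=counts_out, config=config, keep_fraction=keep_fraction
    )


def predict_mode(
    dictionary: MoveletDictionary, query: Movelet, config: MoveletConfig | None = None
) -> tuple[str, float]:
    """Nearest-chapter classification of one (scaled) query movelet.

    Returns the mode of the chapter containing the closest movelet and
    that minimal distance.  Ties are broken by canonical mode order,
    then by the earlier source time within a chapter.
    """
    config = config or dictionary.config
    best_mode, best_d = None, np.inf
    for mode in MODES:
        chapter = dictionary.chapters.get(mode, [])
        if not chapter:
            continue
        sp, ac = _stack(chapter)
        if sp.shape[1] != len(query.speed):
            raise ValueError("query window length does not match dictionary H")
        d = (
            np.linalg.norm(ac - query.accel, axis=1) / config.fa
            + np.linalg.norm(sp - query.speed, axis=1) / config.fs
        )
        dmin = float(d.min())
        if dmin < best_d - 1e-12:
            best_mode, best_d = mode, dmin
    if best_mode is None:
        raise ValueError("dictionary has no movelets")
    return best_mode, best_d


def predict_modes(dictionary: MoveletDictionary, queries: list[Movelet]) -> list[str]:
    """Vectorized nearest-chapter prediction for many queries."""
    config = dictionary.config
    if not queries:
        return []
    best_d = np.full(len(queries), np.inf)
    best_mode = np.empty(len(queries), dtype=object)
    for mode in MODES:
        chapter = dictionary.chapters.get(mode, [])
        if not chapter:
            continue
        d = _distance_matrix(queries, chapter, config).min(axis=1)
        better = d < best_d - 1e-12
        best_d[better] = d[better]
        best_mode[better] = mode
    return list(best_mode)


def evaluate_movelets(dictionary: MoveletDictionary, test: list[Movelet]):
    """Row-normalized confusion proportions and overall accuracy.

    Test movelets must already be scaled with the training scaler.
    Returns ``(confusion, accuracy)`` where ``confusion`` is a DataFrame
    indexed by true mode with one column per predicted mode, rows
    summing to 1 (rows of unobserved modes are dropped).
    """
    import pandas as pd

    preds = predict_modes(dictionary, test)
    truth = [m.mode for m in test]
    counts = pd.crosstab(
        pd.Categorical(truth, categories=MODES),
        pd.Categorical(preds, categories=MODES),
        dropna=False,
    )
    counts.index = pd.Index(MODES, name="true")
    counts.columns = pd.Index(MODES, name="predicted")
    totals = counts.sum(axis=1)
    confusion = counts.div(totals.replace(0, np.nan), axis=0).dropna(how="all")
    accuracy = float(np.mean([p == t for p, t in zip(preds, truth)])) if test else float("nan")
    return confusion, accuracy


def train_dictionary(
    train_movelets: list[Movelet],
    validation_movelets: list[Movelet],
    config: MoveletConfig,
    keep_fraction: float = 0.5,
) -> MoveletDictionary:
    """Fit scaler, match validation movelets, refine, and package."""
    scaler = ChannelScaler.fit(train_movelets)
    tr = scaler.transform_all(train_movelets)
    va = scaler.transform_all(validation_movelets)
    counts = match_validation(tr, va, config)
    dictionary = refine_dictionary(tr, counts, config, keep_fraction)
    dictionary.scaler = scaler
    return dictionary
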