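"""Movelet generation, scaling, matching, refinement and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movemode.core import MODES, Trip
from movemode.movelets import (
    ChannelScaler,
    Movelet,
    MoveletConfig,
    MoveletDictionary,
    generate_chapter,
    match_validation,
    movelet_distance,
    predict_mode,
    predict_modes,
    refine_dictionary,
    evaluate_movelets,
    train_dictionary,
)


def make_trip(T, mode="walk", seed=0, trip_id="t0"):
    rng = np.random.default_rng(seed)
    return Trip(trip_id, mode, rng.uniform(0, 30, T), rng.uniform(8, 12, 5 * T))


def make_movelet(H, mode="walk", seed=0, end_t=0, config=None):
    cfg = config or MoveletConfig(H=H)
    rng = np.random.default_rng(seed)
    return Movelet(rng.uniform(0, 1, H * cfg.fs), rng.uniform(0, 1, H * cfg.fa), mode, "t", end_t)


class TestGenerateChapter:
    def test_sixty_second_trip_seven_movelets(self):
        cfg = MoveletConfig(H=30, delta=5)
        assert len(generate_chapter(make_trip(60), cfg)) == 7

    def test_trip_equal_to_window_yields_one(self):
        cfg = MoveletConfig(H=30, delta=5)
        assert len(generate_chapter(make_trip(30), cfg)) == 1

    def test_window_point_counts(self):
        cfg = MoveletConfig(H=30, delta=5)
        m = generate_chapter(make_trip(60), cfg)[0]
        assert len(m.speed) == 30 and len(m.accel) == 150

    def test_short_trip_empty(self):
        assert generate_chapter(make_trip(20), MoveletConfig(H=30)) == []

    @given(
        delta=st.integers(1, 6),
        mult=st.integers(1, 8),
        extra=st.integers(0, 40),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_count_formula(self, delta, mult, extra):
        H = delta * mult
        T = H + extra
        cfg = MoveletConfig(H=H, delta=delta)
        got = len(generate_chapter(make_trip(T), cfg))
        assert got == (T - H) // delta + 1

    def test_interior_second_membership(self):
        # every interior second is covered by H/delta overlapping windows
        cfg = MoveletConfig(H=30, delta=5)
        trip = make_trip(120)
        counts = np.zeros(120)
        for m in generate_chapter(trip, cfg):
            counts[m.end_t - cfg.H : m.end_t] += 1
        interior = counts[cfg.H - cfg.delta : 120 - cfg.H + cfg.delta]
        assert (interior == cfg.H // cfg.delta).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MoveletConfig(H=31, delta=5)
        with pytest.raises(ValueError):
            MoveletConfig(H=4, delta=5)


class TestScaler:
    def test_midpoint_maps_to_half(self):
        tr = [Movelet(np.array([0.0, 60.0]), np.linspace(0, 20, 10), "walk", "t", 2)]
        sc = ChannelScaler.fit(tr)
        out = sc.transform(Movelet(np.array([30.0, 30.0]), np.zeros(10), "walk", "t", 2))
        assert np.allclose(out.speed, 0.5)

    def test_clipping_below_min(self):
        tr = [Movelet(np.array([10.0, 60.0]), np.linspace(5, 20, 10), "walk", "t", 2)]
        sc = ChannelScaler.fit(tr)
        out = sc.transform(Movelet(np.array([0.0, 0.0]), np.zeros(10), "walk", "t", 2))
        assert (out.speed == 0.0).all() and (out.accel == 0.0).all()

    def test_refit_on_scaled_data_is_identity(self):
        rng = np.random.default_rng(0)
        tr = [Movelet(rng.uniform(0, 60, 5), rng.uniform(5, 15, 25), "walk", "t", i) for i in range(4)]
        scaled = ChannelScaler.fit(tr).transform_all(tr)
        sc2 = ChannelScaler.fit(scaled)
        again = sc2.transform_all(scaled)
        for a, b in zip(scaled, again):
            assert np.allclose(a.speed, b.speed) and np.allclose(a.accel, b.accel)

    def test_constant_channel_rejected(self):
        tr = [Movelet(np.full(3, 5.0), np.linspace(0, 1, 15), "walk", "t", 3)]
        with pytest.raises(ValueError, match="speed"):
            ChannelScaler.fit(tr)


class TestDistance:
    cfg = MoveletConfig(H=30, delta=5)

    def test_identity(self):
        m = make_movelet(30, seed=1)
        assert movelet_distance(m, m, self.cfg) == 0.0

    def test_single_point_speed_difference(self):
        x = make_movelet(30, seed=2)
        y = Movelet(x.speed.copy(), x.accel.copy(), x.mode, x.trip_id, x.end_t)
        y.speed[7] += 1.0
        assert movelet_distance(x, y, self.cfg) == pytest.approx(1.0)

    def test_symmetry_and_homogeneity(self):
        x, y = make_movelet(30, seed=3), make_movelet(30, seed=4)
        d = movelet_distance(x, y, self.cfg)
        assert d == pytest.approx(movelet_distance(y, x, self.cfg))
        z = Movelet(y.speed + 2 * (x.speed - y.speed), y.accel + 2 * (x.accel - y.accel),
                    y.mode, y.trip_id, y.end_t)
        # doubling every coordinate difference doubles the distance
        assert movelet_distance(x, z, self.cfg) == pytest.approx(d)

    def test_mismatched_h_rejected(self):
        with pytest.raises(ValueError):
            movelet_distance(make_movelet(30), make_movelet(60), self.cfg)


class TestMatchValidation:
    cfg = MoveletConfig(H=10, delta=5)

    def test_single_training_movelet_gets_all(self):
        tr = [make_movelet(10, seed=0)]
        va = [make_movelet(10, mode=m, seed=i) for i, m in enumerate(MODES)]
        counts = match_validation(tr, va, self.cfg)
        assert counts.sum() == len(va) and counts.shape == (1, 5)

    def test_identical_movelet_matches_itself(self):
        tr = [make_movelet(10, seed=i) for i in range(5)]
        va = [Movelet(tr[3].speed.copy(), tr[3].accel.copy(), "bike", "v", 0)]
        counts = match_validation(tr, va, self.cfg)
        assert counts[3, MODES.index("bike")] == 1 and counts.sum() == 1

    def test_conservation_against_brute_force(self):
        rng = np.random.default_rng(5)
        tr = [make_movelet(10, seed=i) for i in range(8)]
        va = [make_movelet(10, mode=MODES[i % 5], seed=100 + i) for i in range(20)]
        counts = match_validation(tr, va, self.cfg)
        assert counts.sum() == len(va)
        brute = np.zeros_like(counts)
        for v in va:
            dists = [movelet_distance(v, t, self.cfg) for t in tr]
            brute[int(np.argmin(dists)), MODES.index(v.mode)] += 1
        assert (counts == brute).all()

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            match_validation([], [make_movelet(10)], self.cfg)


class TestRefineDictionary:
    cfg = MoveletConfig(H=10, delta=5)

    def test_ambiguous_movelet_removed_everywhere(self):
        tr = [make_movelet(10, mode="car", seed=i) for i in range(3)]
        counts = np.zeros((3, 5), dtype=int)
        counts[0, MODES.index("car")] = 5
        counts[1, MODES.index("car")] = 2
        counts[1, MODES.index("bus")] = 2  # ambiguous
        counts[2, MODES.index("bus")] = 3
        d = refine_dictionary(tr, counts, self.cfg, keep_fraction=1.0)
        assert len(d.chapters["car"]) == 1 and d.chapters["car"][0] is tr[0]
        assert len(d.chapters["bus"]) == 1 and d.chapters["bus"][0] is tr[2]

    def test_keep_fraction_truncates_to_top_half(self):
        tr = [make_movelet(10, mode="walk", seed=i, end_t=i) for i in range(10)]
        counts = np.zeros((10, 5), dtype=int)
        counts[:, 0] = np.arange(10, 0, -1)  # distinct counts, movelet 0 highest
        d = refine_dictionary(tr, counts, self.cfg, keep_fraction=0.5)
        assert [m.end_t for m in d.chapters["walk"]] == [0, 1, 2, 3, 4]

    def test_never_grows_and_subset_of_training(self):
        rng = np.random.default_rng(6)
        tr = [make_movelet(10, mode=MODES[i % 5], seed=i, end_t=i) for i in range(30)]
        # sparse counts: most movelets matched by one mode, some by two
        counts = np.zeros((30, 5), dtype=int)
        for i in range(30):
            if rng.random() < 0.8:
                counts[i, i % 5] = int(rng.integers(1, 6))
            if rng.random() < 0.25:
                counts[i, int(rng.integers(0, 5))] = int(rng.integers(1, 4))
        formed = {m: int((counts[:, k] > 0).sum()) for k, m in enumerate(MODES)}
        d = refine_dictionary(tr, counts, self.cfg, keep_fraction=0.4)
        for k, m in enumerate(MODES):
            assert len(d.chapters[m]) <= formed[m]
            assert all(any(mov is x for x in tr) for mov in d.chapters[m])

    def test_bad_keep_fraction(self):
        with pytest.raises(ValueError):
            refine_dictionary([make_movelet(10)], np.ones((1, 5), dtype=int), self.cfg, 0.0)


class TestPredict:
    cfg = MoveletConfig(H=10, delta=5)

    def _dictionary(self, seed=0, per_mode=4):
        rng = np.random.default_rng(seed)
        chapters = {
            m: [make_movelet(10, mode=m, seed=int(rng.integers(1 << 30)), end_t=j)
                for j in range(per_mode)]
            for m in MODES
        }
        return MoveletDictionary(chapters=chapters,
                                 counts={m: np.ones(per_mode, int) for m in MODES},
                                 config=self.cfg)

    def test_exact_member_query(self):
        d = self._dictionary()
        q = d.chapters["walk"][2]
        mode, dist = predict_mode(d, q, self.cfg)
        assert mode == "walk" and dist == 0.0

    def test_single_chapter_forced(self):
        d = self._dictionary()
        d.chapters = {"rail": d.chapters["rail"]}
        mode, _ = predict_mode(d, make_movelet(10, seed=99), self.cfg)
        assert mode == "rail"

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            d = self._dictionary(seed=trial, per_mode=int(rng.integers(1, 6)))
            q = make_movelet(10, seed=1000 + trial)
            mode, dist = predict_mode(d, q, self.cfg)
            best = min(
                ((m, movelet_distance(q, mov, self.cfg))
                 for m in MODES for mov in d.chapters[m]),
                key=lambda t: (t[1], MODES.index(t[0])),
            )
            assert mode == best[0] and dist == pytest.approx(best[1])

    def test_batch_prediction_matches_single(self):
        d = self._dictionary(seed=3)
        qs = [make_movelet(10, seed=i) for i in range(10)]
        batch = predict_modes(d, qs)
        single = [predict_mode(d, q, self.cfg)[0] for q in qs]
        assert batch == single


class TestEvaluate:
    cfg = MoveletConfig(H=10, delta=5)

    def test_perfect_dictionary_identity_confusion(self):
        chapters = {m: [make_movelet(10, mode=m, seed=i)] for i, m in enumerate(MODES)}
        d = MoveletDictionary(chapters=chapters,
                              counts={m: np.ones(1, int) for m in MODES}, config=self.cfg)
        test = [chapters[m][0] for m in MODES]
        confusion, acc = evaluate_movelets(d, test)
        assert acc == 1.0
        assert np.allclose(np.diag(confusion.to_numpy()), 1.0)

    def test_rows_sum_to_one_and_tally(self):
        rng = np.random.default_rng(9)
        chapters = {m: [make_movelet(10, mode=m, seed=100 + i)] for i, m in enumerate(MODES)}
        d = MoveletDictionary(chapters=chapters,
                              counts={m: np.ones(1, int) for m in MODES}, config=self.cfg)
        test = [make_movelet(10, mode=MODES[i % 5], seed=i) for i in range(40)]
        confusion, acc = evaluate_movelets(d, test)
        assert np.allclose(confusion.sum(axis=1), 1.0)
        preds = predict_modes(d, test)
        assert acc == pytest.approx(np.mean([p == t.mode for p, t in zip(preds, test)]))


class TestEndToEnd:
    def test_well_separated_modes_high_recall(self):
        # walk at ~3 mph vs bike at ~12 mph with distinct vibration: a
        # refined dictionary should recover held-out movelets of both
        # modes nearly perfectly.
        from movemode.synthgen import DEFAULT_PROFILES, simulate_trip
        from movemode import preprocess as pp

        cfg = MoveletConfig(H=30, delta=5)
        trips = []
        for k in range(4):
            trips.append(simulate_trip(DEFAULT_PROFILES["walk"], 400, seed=k, trip_id=f"w{k}"))
            trips.append(simulate_trip(DEFAULT_PROFILES["bike"], 400, seed=100 + k, trip_id=f"b{k}"))
        movs = [m for t in trips for m in generate_chapter(t, cfg)]
        assignment = pp.split_dataset(range(len(movs)), seed=2).assignment
        parts = {p: [movs[i] for i in range(len(movs)) if assignment[i] == p]
                 for p in ("train", "validation", "test")}
        d = train_dictionary(parts["train"], parts["validation"], cfg, keep_fraction=0.5)
        confusion, acc = evaluate_movelets(d, d.scaler.transform_all(parts["test"]))
        assert confusion.loc["walk", "walk"] >= 0.9
        assert confusion.loc["bike", "bike"] >= 0.9

    def test_save_load_round_trip(self, tmp_path):
        cfg = MoveletConfig(H=10, delta=5)
        chapters = {m: [make_movelet(10, mode=m, seed=i)] for i, m in enumerate(MODES)}
        d = MoveletDictionary(chapters=chapters,
                              counts={m: np.ones(1, int) for m in MODES},
                              scaler=ChannelScaler(0, 60, 3, 17), config=cfg)
        d.save(tmp_path / "dict")
        d2 = MoveletDictionary.load(tmp_path / "dict")
        q = make_movelet(10, seed=55)
        assert predict_mode(d, q, cfg) == predict_mode(d2, q, cfg)
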