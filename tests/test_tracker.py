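"""Tracker contracts: the matching criteria (distance cutoff, length factor,
visual similarity, cost), greedy frame matching against an exhaustive
assignment oracle, gap/retention rules, and full-scene recovery on the
simulator with oracle embeddings."""

import itertools

import numpy as np
import pandas as pd
import pytest

from combtrack import simulator, tracker
from combtrack.tracker import (MatchStats, Trajectory, TrackerParams,
                               angle_difference_term, close_stale,
                               distance_cutoff, length_factor, match_frame,
                               pair_cost, score_against_truth, track,
                               track_parallel, visual_similarity)

PARAMS = TrackerParams()


def make_traj(tid, points, bs=None, t0=0.0, fps=10.0, embeddings=None):
    tr = Trajectory(tid)
    for k, (x, y) in enumerate(points):
        b = bs[k] if bs is not None else 1
        emb = embeddings[k] if embeddings is not None else None
        tr.append(k, t0 + k / fps, x, y, b, 0.0 if b == 1 else None, k, emb)
    return tr


class TestDistanceCutoff:
    def test_full_bee_one_frame_gap_is_half_body_length(self):
        tr = make_traj(0, [(10, 10)] * 3)
        assert distance_cutoff(tr, tr.ts[-1] + 0.1, PARAMS) == pytest.approx(40.0)

    def test_cell_bee_history_uses_a_third(self):
        tr = make_traj(0, [(10, 10)] * 6, bs=[2] * 6)
        for dt in (0.1, 0.4, 2.0):
            assert distance_cutoff(tr, tr.ts[-1] + dt, PARAMS) == \
                pytest.approx(40.0 / 3.0)

    def test_square_root_growth_with_gap(self):
        tr = make_traj(0, [(10, 10)] * 3)
        assert distance_cutoff(tr, tr.ts[-1] + 0.4, PARAMS) == pytest.approx(80.0)

    def test_majority_vote_over_last_ten(self):
        # 6 cell in the last 10 -> cell rule, even with a full-bee prefix
        tr = make_traj(0, [(0, 0)] * 12, bs=[1, 1] + [2] * 6 + [1] * 4)
        assert distance_cutoff(tr, tr.ts[-1] + 0.1, PARAMS) == \
            pytest.approx(40.0 / 3.0)
        # full-bee majority in the window -> full-bee rule
        tr2 = make_traj(1, [(0, 0)] * 12, bs=[2, 2] + [1] * 6 + [2] * 2 + [1] * 2)
        assert distance_cutoff(tr2, tr2.ts[-1] + 0.1, PARAMS) == pytest.approx(40.0)

    def test_non_increasing_time_rejected(self):
        tr = make_traj(0, [(0, 0)])
        with pytest.raises(ValueError):
            distance_cutoff(tr, tr.ts[-1], PARAMS)


class TestLengthFactor:
    @pytest.mark.parametrize("traj_len,max_len,expected",
                             [(10, 10, 0.0), (0, 10, 30.0), (5, 10, 15.0)])
    def test_reference_values(self, traj_len, max_len, expected):
        assert length_factor(traj_len, max_len, 30.0) == pytest.approx(expected)

    def test_no_trajectories_yet(self):
        assert length_factor(0, 0, 30.0) == 0.0

    def test_bounded_by_scale(self):
        for n in range(11):
            assert 0.0 <= length_factor(n, 10, 30.0) <= 30.0


class TestVisualSimilarity:
    def test_exact_match_gives_zero(self):
        e = np.eye(12, 4)
        tr = make_traj(0, [(0, 0)] * 12, embeddings=list(e))
        assert visual_similarity(tr, e[-1], lookback=10) == 0.0

    def test_length_one_trajectory(self):
        tr = make_traj(0, [(0, 0)], embeddings=[np.array([1.0, 0.0])])
        assert visual_similarity(tr, np.array([0.0, 0.0])) == pytest.approx(1.0)

    def test_window_excludes_older_embeddings(self):
        # closest embedding sits 11 steps back -> outside the 10-step window
        embs = [np.array([0.0, 0.0])] + [np.array([5.0, 0.0])] * 11
        tr = make_traj(0, [(0, 0)] * 12, embeddings=embs)
        v10 = visual_similarity(tr, np.array([0.0, 0.0]), lookback=10)
        v_full = min(float(np.sum((e - 0.0) ** 2)) for e in embs)
        assert v10 == pytest.approx(25.0)
        assert v_full == 0.0


class TestPairCost:
    def test_embedding_mode_arithmetic(self):
        assert pair_cost(30.0, 0.5, 0.0, "embedding") == pytest.approx(1.49)

    def test_position_mode_has_no_distance_scaling(self):
        assert pair_cost(10.0, None, 15.0, "position") == pytest.approx(25.0)

    def test_angle_term_adds_quarter_at_half_turn(self):
        d_a = angle_difference_term(0.0, 180.0)
        base = pair_cost(0.0, 0.0, 0.0, "embedding")
        with_angle = pair_cost(0.0, 0.0, 0.0, "embedding+angle", d_a)
        assert with_angle - base == pytest.approx(0.25)

    def test_missing_v_in_embedding_mode_rejected(self):
        with pytest.raises(ValueError):
            pair_cost(1.0, None, 0.0, "embedding")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pair_cost(1.0, None, 0.0, "nearest")


def _frame_df(points, t=0.1, frame=1, bs=None, alphas=None):
    n = len(points)
    return pd.DataFrame({
        "index": np.arange(n), "frame": frame, "t": t,
        "x": [p[0] for p in points], "y": [p[1] for p in points],
        "b": bs or [1] * n, "alpha": alphas or [np.nan] * n,
    })


class TestMatchFrame:
    def test_single_in_range_detection_matches(self):
        tr = make_traj(0, [(50, 50)])
        out = match_frame([tr], _frame_df([(55, 50)]), PARAMS, "position")
        assert out == {0: tr}

    def test_out_of_range_detection_left_unmatched(self):
        tr = make_traj(0, [(50, 50)])
        out = match_frame([tr], _frame_df([(300, 300)]), PARAMS, "position")
        assert out == {}

    def test_crossing_resolved_by_embeddings_not_by_position(self):
        # trajectories A and B approach; at the match frame the detection of A
        # is slightly nearer to B and vice versa — position-only greedy swaps,
        # the appearance cutoff (wrong-pair V > c_v) forbids the swap
        eA, eB = np.zeros(8), np.zeros(8)
        eA[0] = eB[1] = 2.0  # squared distance 8 between identities
        trA = make_traj(0, [(40 + 2 * k, 50) for k in range(5)],
                        embeddings=[eA] * 5)
        trB = make_traj(1, [(60 - 2 * k, 50) for k in range(5)],
                        embeddings=[eB] * 5)
        det = _frame_df([(52, 50), (48, 50)], t=0.5)  # A is at 52, B at 48
        emb = np.stack([eA, eB])
        pos = match_frame([trA, trB], det, PARAMS, "position")
        assert pos[1] is trA and pos[0] is trB  # swapped
        vis = match_frame([trA, trB], det, PARAMS, "embedding", emb)
        assert vis[0] is trA and vis[1] is trB  # corrected

    def test_greedy_matches_exhaustive_on_dominant_diagonal(self):
        # on instances whose cost matrix has a dominant diagonal the greedy
        # matching equals the exhaustive minimum-cost assignment
        rng = np.random.default_rng(8)
        for trial in range(20):
            n = int(rng.integers(2, 7))
            while True:  # dominant diagonal needs separated anchors
                base = rng.uniform(0, 200, (n, 2))
                d = np.hypot(*(base[:, None] - base[None]).transpose(2, 0, 1))
                if n == 1 or d[np.triu_indices(n, 1)].min() > 30:
                    break
            trajs = [make_traj(i, [tuple(base[i])] * 3) for i in range(n)]
            jitter = rng.uniform(-3, 3, (n, 2))
            det_pts = [tuple(base[i] + jitter[i]) for i in range(n)]
            det = _frame_df(det_pts, t=0.4)
            got = match_frame(trajs, det, PARAMS, "position")
            # exhaustive oracle over permutations of the admissible cost matrix
            C = np.full((n, n), np.inf)
            for i, tr in enumerate(trajs):
                c_d = distance_cutoff(tr, 0.4, PARAMS)
                for j, p in enumerate(det_pts):
                    E = np.hypot(p[0] - tr.xs[-1], p[1] - tr.ys[-1])
                    if E <= c_d:
                        C[i, j] = E  # equal lengths -> l identical, ignorable
            best, best_cost = None, np.inf
            for perm in itertools.permutations(range(n)):
                cost = sum(C[i, perm[i]] for i in range(n))
                if cost < best_cost:
                    best, best_cost = perm, cost
            assert np.isfinite(best_cost)
            for i in range(n):
                assert got[best[i]] is trajs[i]

    def test_raising_cv_never_rejects_more_pairs(self):
        rng = np.random.default_rng(9)
        trajs = [make_traj(i, [(float(rng.uniform(0, 100)),
                                float(rng.uniform(0, 100)))] * 2,
                           embeddings=[rng.standard_normal(4)] * 2)
                 for i in range(6)]
        det = _frame_df([(float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
                         for _ in range(6)], t=0.3)
        emb = rng.standard_normal((6, 4))
        rejected = []
        for c_v in (0.5, 1.75, 5.0):
            p = TrackerParams(c_v=c_v)
            stats = MatchStats()
            match_frame(trajs, det, p, "embedding", emb, stats)
            rejected.append(stats.n_rejected_appearance)
        assert rejected[0] >= rejected[1] >= rejected[2]


class TestCloseStale:
    def test_cell_bee_survives_eight_second_gap(self):
        tr = make_traj(0, [(0, 0)] * 8, bs=[2] * 8)
        still, fin, dis = close_stale([tr], tr.ts[-1] + 8.0, PARAMS)
        assert still == [tr]

    def test_default_gap_discards_short_trajectory(self):
        tr = make_traj(0, [(0, 0)] * 400)  # 40 s at 10 FPS
        still, fin, dis = close_stale([tr], tr.ts[-1] + 3.1, PARAMS)
        assert dis == [tr] and tr.status == "discarded"

    def test_entrance_gap_finishes_long_trajectory(self):
        params = TrackerParams(entrance_region=simulator.DiskRegion(0, 0, 50))
        tr = make_traj(0, [(10, 10)] * 700)  # 70 s, ends near the entrance
        still, fin, dis = close_stale([tr], tr.ts[-1] + 1.1, params)
        assert fin == [tr] and tr.status == "finished"

    def test_entrance_gap_still_open_before_cutoff(self):
        params = TrackerParams(entrance_region=simulator.DiskRegion(0, 0, 50))
        tr = make_traj(0, [(10, 10)] * 700)
        still, _, _ = close_stale([tr], tr.ts[-1] + 0.9, params)
        assert still == [tr]


class TestTrack:
    def test_single_bee_yields_one_full_trajectory(self):
        n = 700  # 70 s
        det = pd.DataFrame({"frame": np.arange(n), "t": np.arange(n) / 10.0,
                            "x": 50.0 + 0.1 * np.arange(n), "y": 50.0,
                            "b": 1, "alpha": 0.0})
        trajs = track(det, PARAMS, "position")
        assert len(trajs) == 1 and len(trajs[0]) == n

    def test_unsorted_input_rejected(self):
        det = pd.DataFrame({"frame": [1, 0], "t": [0.1, 0.0], "x": [0, 0],
                            "y": [0, 0], "b": [1, 1], "alpha": [0, 0]})
        with pytest.raises(ValueError):
            track(det, PARAMS, "position")

    def test_far_detection_seeds_new_trajectory(self):
        det = pd.DataFrame({
            "frame": [0, 1, 1], "t": [0.0, 0.1, 0.1],
            "x": [0.0, 1.0, 500.0], "y": [0.0, 0.0, 500.0],
            "b": 1, "alpha": np.nan})
        fin, dis, opened, _ = tracker._track_core(det, PARAMS, "position", None,
                                                  0, flush=False)
        assert len(opened) == 2


class TestSceneRecovery:
    def test_embedding_mode_recovers_identities_and_beats_position(self, tracking_scene):
        truth, det, E = tracking_scene
        params = TrackerParams(entrance_region=truth.config.entrance_region())
        emb_trajs = track(det, params, "embedding", E)
        pos_trajs = track(det, params, "position")
        s_emb = score_against_truth(emb_trajs, det)
        s_pos = score_against_truth(pos_trajs, det)
        assert s_emb["proportion"] >= 0.95
        assert s_pos["n_correct"] < s_emb["n_correct"]

    def test_parallel_tracking_matches_serial(self, tracking_scene):
        truth, det, E = tracking_scene
        params = TrackerParams(entrance_region=truth.config.entrance_region())
        serial = track(det, params, "embedding", E)
        parallel = track_parallel(det, params, "embedding", E)
        serial_sets = {frozenset(tr.rows) for tr in serial}
        identical = sum(1 for tr in parallel if frozenset(tr.rows) in serial_sets)
        assert identical >= 0.95 * len(serial)

    def test_lower_frame_rate_degrades_recovery(self, tracking_scene):
        truth, det, E = tracking_scene
        params = TrackerParams(entrance_region=truth.config.entrance_region())
        full = score_against_truth(track(det, params, "embedding", E), det)
        keep = det["frame"] % 5 == 0  # 10 -> 2 FPS
        det2 = det[keep].reset_index(drop=True)
        E2 = E[keep.to_numpy()]
        params2 = TrackerParams(entrance_region=truth.config.entrance_region(),
                                fps=2.0)
        sub = score_against_truth(track(det2, params2, "embedding", E2), det2)
        assert sub["proportion"] < full["proportion"]

    def test_no_detection_shared_between_trajectories(self, tracking_scene):
        truth, det, E = tracking_scene
        params = TrackerParams(entrance_region=truth.config.entrance_region())
        trajs = track(det, params, "embedding", E)
        rows = [r for tr in trajs for r in tr.rows]
        assert len(rows) == len(set(rows))


class TestScoring:
    def _perfect_scene(self):
        cfg = simulator.SimConfig(n_bees=5, arena=(512, 512), duration_s=70.0,
                                  seed=3, cell_rate=0.0)
        truth = simulator.simulate_trajectories(cfg)
        det = truth.detections()
        return truth, det

    def test_perfect_trajectories_score_one(self):
        truth, det = self._perfect_scene()
        trajs = []
        d = det.reset_index(drop=True)
        for tid, g in d.groupby("truth_id"):
            tr = Trajectory(int(tid))
            for ridx, r in g.iterrows():
                tr.append(r["frame"], r["t"], r["x"], r["y"], r["b"], r["alpha"], ridx)
            trajs.append(tr)
        s = score_against_truth(trajs, det)
        assert s["proportion"] == pytest.approx(1.0)

    def test_low_majority_trajectory_not_counted(self):
        truth, det = self._perfect_scene()
        d = det.reset_index(drop=True)
        g0 = d[d.truth_id == 0].reset_index()
        g1 = d[d.truth_id == 1].reset_index()
        tr = Trajectory(0)
        n = len(g0)
        k = int(0.75 * n)  # 75% majority < 80% rule
        for i in range(k):
            r = g0.iloc[i]
            tr.append(r["frame"], r["t"], r["x"], r["y"], r["b"], r["alpha"], r["index"])
        for i in range(k, n):
            r = g1.iloc[i]
            tr.append(r["frame"], r["t"], r["x"], r["y"], r["b"], r["alpha"], r["index"])
        s = score_against_truth([tr], det)
        assert s["n_correct"] == 0

    def test_identity_credited_at_most_once(self):
        truth, det = self._perfect_scene()
        d = det.reset_index(drop=True)
        g0 = d[d.truth_id == 0].reset_index()
        half = len(g0) // 2
        frags = []
        for lo, hi in ((0, half), (half, len(g0))):
            tr = Trajectory(lo)
            for i in range(lo, hi):
                r = g0.iloc[i]
                tr.append(r["frame"], r["t"], r["x"], r["y"], r["b"], r["alpha"],
                          r["index"])
            frags.append(tr)
        s = score_against_truth(frags, det, coverage=0.4)
        assert s["n_correct"] <= 1
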