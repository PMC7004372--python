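import numpy as np
import pytest

from stimnet.connectome import generate_connectome
from stimnet.engine import MINUTE_MS, SECOND_MS, SnapshotSeries
from stimnet.metrics import (
    EffectSeries,
    PairingError,
    detect_secondary_excitation,
    effect_series,
    global_effect,
    jaccard_pair,
    local_effect,
    node_ranking,
    persistence_rate,
    secondary_jaccard,
    stabilization_time,
)


def make_pair(W_stim, W_nostim, w_stim=None, w_nostim=None, times=None):
    W_stim = np.asarray(W_stim, float)
    W_nostim = np.asarray(W_nostim, float)
    T, n, _ = W_stim.shape
    if w_stim is None:
        w_stim = np.full((T, n, 7), 1 / 7)
    if w_nostim is None:
        w_nostim = np.full((T, n, 7), 1 / 7)
    times = np.arange(T) * 50.0 * SECOND_MS if times is None else np.asarray(times)
    prov = {"pair_hash": "x"}
    stim = SnapshotSeries(times, W_stim, np.asarray(w_stim, float), "stimulated", dict(prov))
    nostim = SnapshotSeries(times, W_nostim, np.asarray(w_nostim, float), "unstimulated", dict(prov))
    return stim, nostim


class TestGlobalEffect:
    def test_identical_matrices(self, rng):
        W = rng.uniform(0, 1, (3, 4, 4))
        stim, nostim = make_pair(W, W.copy())
        assert np.allclose(global_effect(stim, nostim), 0.0)

    def test_uniform_scaling(self, rng):
        W = rng.uniform(0.1, 1, (2, 5, 5))
        stim, nostim = make_pair(1.1 * W, W)
        assert np.allclose(global_effect(stim, nostim), 10.0, atol=1e-9)

    def test_matches_brute_force(self, rng):
        Wp = rng.uniform(0, 1, (1, 5, 5))
        W = rng.uniform(0.1, 1, (1, 5, 5))
        stim, nostim = make_pair(Wp, W)
        num = sum(abs(Wp[0, i, j] - W[0, i, j]) for i in range(5) for j in range(5))
        den = sum(abs(W[0, i, j]) for i in range(5) for j in range(5))
        assert global_effect(stim, nostim)[0] == pytest.approx(100 * num / den, abs=1e-12)

    def test_denominator_scale_invariance(self, rng):
        W = rng.uniform(0.1, 1, (2, 4, 4))
        Wp = W + rng.uniform(0, 0.1, W.shape)
        s1, n1 = make_pair(Wp, W)
        s2, n2 = make_pair(7.3 * Wp, 7.3 * W)
        assert np.allclose(global_effect(s1, n1), global_effect(s2, n2), atol=1e-9)

    def test_timestamp_mismatch_rejected(self, rng):
        W = rng.uniform(0, 1, (3, 4, 4))
        stim, nostim = make_pair(W, W)
        nostim.times_ms = nostim.times_ms + 1.0
        with pytest.raises(PairingError):
            global_effect(stim, nostim)

    def test_provenance_mismatch_rejected(self, rng):
        W = rng.uniform(0, 1, (3, 4, 4))
        stim, nostim = make_pair(W, W)
        nostim.provenance["pair_hash"] = "y"
        with pytest.raises(PairingError):
            global_effect(stim, nostim)


class TestLocalEffect:
    def test_equal_weights(self, rng):
        W = rng.uniform(0, 1, (2, 3, 3))
        stim, nostim = make_pair(W, W)
        assert np.allclose(local_effect(stim, nostim), 0.0)

    def test_single_entry_difference(self):
        w = np.full((1, 1, 7), 1 / 7)
        wp = w.copy()
        wp[0, 0, 2] += 0.07
        stim, nostim = make_pair(np.ones((1, 1, 1)), np.ones((1, 1, 1)), wp, w)
        assert local_effect(stim, nostim)[0, 0] == pytest.approx(7.0, abs=1e-9)

    def test_matches_brute_force(self, rng):
        w = rng.uniform(0.05, 0.3, (1, 4, 7))
        wp = w + rng.uniform(-0.02, 0.02, w.shape)
        stim, nostim = make_pair(np.ones((1, 4, 4)), np.ones((1, 4, 4)), wp, w)
        d = local_effect(stim, nostim)
        for i in range(4):
            num = sum(abs(wp[0, i, k] - w[0, i, k]) for k in range(7))
            den = sum(abs(w[0, i, k]) for k in range(7))
            assert d[0, i] == pytest.approx(100 * num / den, abs=1e-12)


class TestPersistenceRate:
    def test_arithmetic(self):
        times = np.array([0.0, 1.0, 2.0])
        assert persistence_rate(times, np.array([1.0, 2.0, 4.0]), 1.0, 2.0) == 0.5

    def test_constant_trace(self):
        times = np.arange(5.0)
        assert persistence_rate(times, np.full(5, 3.3), 1.0, 4.0) == pytest.approx(1.0)

    def test_nearest_snapshot_lookup(self):
        times = np.array([0.0, 50.0, 100.0])
        D = np.array([1.0, 2.0, 8.0])
        # t0 = 60 resolves to snapshot at 50
        assert persistence_rate(times, D, 60.0, 100.0) == pytest.approx(0.25)

    def test_zero_final_value_rejected(self):
        with pytest.raises(ZeroDivisionError):
            persistence_rate(np.arange(3.0), np.array([1.0, 1.0, 0.0]), 1.0, 2.0)


class TestStabilization:
    def test_constant_positive_trace(self):
        times = np.arange(0, 20) * 50 * SECOND_MS
        t = stabilization_time(times, np.full(20, 0.4))
        # first snapshot with a full 5-minute trailing window
        assert t == 300 * SECOND_MS

    def test_alternating_trace_never_stabilizes(self):
        times = np.arange(0, 40) * 50 * SECOND_MS
        trace = np.where(np.arange(40) % 2 == 0, 0.05, 0.15)  # CV ~ 0.52
        assert stabilization_time(times, trace) is None

    def test_matches_exhaustive_scan(self, rng):
        times = np.arange(0, 60) * 50 * SECOND_MS
        trace = np.concatenate([np.exp(-np.linspace(0, 5, 30)), np.full(30, 0.01)])
        trace = trace + rng.uniform(0, 1e-4, 60)
        window, thr = 5 * MINUTE_MS, 0.3
        expected = None
        for idx in range(len(times)):
            t = times[idx]
            if t < window:
                continue
            sel = (times > t - window) & (times <= t)
            vals = trace[sel]
            if len(vals) >= 2 and vals.mean() > 0 and vals.std(ddof=1) / vals.mean() < thr:
                expected = t
                break
        assert stabilization_time(times, trace, window, thr) == expected

    def test_zero_trace_not_stabilized(self):
        times = np.arange(0, 20) * 50 * SECOND_MS
        assert stabilization_time(times, np.zeros(20)) is None

    def test_threshold_monotonicity(self, rng):
        times = np.arange(0, 50) * 50 * SECOND_MS
        trace = np.exp(-np.linspace(0, 3, 50)) + rng.uniform(0, 0.05, 50)
        t_loose = stabilization_time(times, trace, cv_threshold=0.5)
        t_tight = stabilization_time(times, trace, cv_threshold=0.1)
        if t_tight is not None:
            assert t_loose is not None and t_loose <= t_tight

    def test_short_trace_warns(self):
        with pytest.warns(UserWarning):
            out = stabilization_time(np.array([0.0, 50.0]), np.array([1.0, 1.0]))
        assert out is None


class TestJaccard:
    def test_identical_neighbourhoods(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 2] = mask[2, 0] = mask[1, 2] = mask[2, 1] = True
        # nodes 0 and 1 both connect exactly to node 2
        assert jaccard_pair(mask, 0, 1) == 1.0

    def test_disjoint_neighbourhoods(self):
        mask = np.zeros((5, 5), bool)
        mask[0, 2] = mask[2, 0] = True
        mask[1, 3] = mask[3, 1] = True
        assert jaccard_pair(mask, 0, 1) == 0.0

    def test_partial_overlap(self):
        # gamma(0) = {2,3,4}, gamma(1) = {3,4,5} -> 2/4
        mask = np.zeros((6, 6), bool)
        for j in (2, 3, 4):
            mask[0, j] = mask[j, 0] = True
        for j in (3, 4, 5):
            mask[1, j] = mask[j, 1] = True
        assert jaccard_pair(mask, 0, 1) == 0.5

    def test_symmetry_and_bounds(self, rng):
        mask = rng.random((8, 8)) < 0.4
        mask = mask | mask.T
        np.fill_diagonal(mask, False)
        for i in range(8):
            for j in range(i + 1, 8):
                v = jaccard_pair(mask, i, j)
                assert v == jaccard_pair(mask, j, i)
                assert 0.0 <= v <= 1.0

    def test_secondary_mean(self):
        mask = np.zeros((8, 8), bool)
        # engineer pairwise values 0.3/0.6/0.9 is fiddly; use brute-force equality
        rng = np.random.default_rng(4)
        mask = rng.random((8, 8)) < 0.5
        mask = mask | mask.T
        np.fill_diagonal(mask, False)
        stim = [0, 1, 2]
        for i in range(3, 8):
            brute = np.mean([jaccard_pair(mask, s, i) for s in stim])
            assert secondary_jaccard(mask, i, stim) == pytest.approx(brute)

    def test_isolated_node_scores_zero(self):
        mask = np.zeros((6, 6), bool)
        mask[0, 1] = mask[1, 0] = True
        assert secondary_jaccard(mask, 5, [0, 1, 2]) == 0.0

    def test_arity_enforced(self):
        mask = np.zeros((6, 6), bool)
        with pytest.raises(ValueError):
            secondary_jaccard(mask, 5, [0, 1])
        secondary_jaccard(mask, 5, [0, 1], allow_any_arity=True)  # ok


class TestNodeRanking:
    @pytest.fixture()
    def ranking_inputs(self):
        conn = generate_connectome(8, seed=9)
        T = 5
        times = np.arange(T) * 50 * SECOND_MS
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 1, (T, 8))
        eff = EffectSeries(times_ms=times, D=rng.uniform(0, 1, T), d=d)
        stim = [0, 1, 2]
        return conn, eff, stim

    def test_columns_match_brute_force(self, ranking_inputs):
        conn, eff, stim = ranking_inputs
        end = 100 * SECOND_MS
        df = node_ranking(conn, eff, stim, end)
        from stimnet.connectome import init_weight_matrix

        W = init_weight_matrix(conn.S)
        Wsym = 0.5 * (W + W.T)
        xyz = conn.regions.centroids()
        for _, row in df.iterrows():
            i = int(row["node"])
            assert i not in stim
            assert row["value_effect_after_stim"] == pytest.approx(eff.d[2, i])
            assert row["value_effect_final"] == pytest.approx(eff.d[-1, i])
            assert row["value_degree"] == conn.mask[i].sum()
            assert row["value_stim_neighbours"] == conn.mask[i, stim].sum()
            denom = Wsym[i].sum()
            want = Wsym[i, stim].sum() / denom if denom > 0 else 0.0
            assert row["value_stim_weight_ratio"] == pytest.approx(want)
            dist = np.mean([np.linalg.norm(xyz[i] - xyz[s]) for s in stim])
            assert row["value_distance_mm"] == pytest.approx(dist)

    def test_ranks_are_permutations(self, ranking_inputs):
        conn, eff, stim = ranking_inputs
        df = node_ranking(conn, eff, stim, 100 * SECOND_MS)
        m = len(df)
        for col in df.columns:
            if col.startswith("rank_"):
                assert sorted(df[col]) == list(range(1, m + 1))

    def test_distance_rank_orientation(self, ranking_inputs):
        conn, eff, stim = ranking_inputs
        df = node_ranking(conn, eff, stim, 100 * SECOND_MS)
        nearest = df.loc[df["rank_distance_mm"] == 1, "value_distance_mm"].iloc[0]
        assert nearest == df["value_distance_mm"].min()

    def test_ties_broken_by_node_order(self, ranking_inputs):
        conn, eff, stim = ranking_inputs
        eff.d[:] = 0.5  # all effects tie
        df = node_ranking(conn, eff, stim, 100 * SECOND_MS)
        sorted_df = df.sort_values("rank_effect_final")
        assert list(sorted_df["node"]) == sorted(df["node"])


class TestSecondaryDetection:
    def _effect(self, d, times=None):
        T = d.shape[0]
        times = np.arange(T) * 50.0 * SECOND_MS if times is None else times
        return EffectSeries(times_ms=times, D=np.zeros(T), d=d)

    def test_identical_traces_no_flags(self):
        d = np.tile(np.linspace(0, 1, 30)[:, None], (1, 6))
        flags = detect_secondary_excitation(self._effect(d), [0], onset_ms=0.0)
        assert flags.empty

    def test_outlier_flagged(self):
        d = np.ones((30, 6)) * 0.1
        d[:, 4] = 1.0
        flags = detect_secondary_excitation(self._effect(d), [0], onset_ms=0.0)
        assert list(flags["node"]) == [4]
        assert flags.iloc[0]["kind"] == "secondary"

    def test_late_step_flagged_as_reexcitation(self):
        T = 40
        d = np.full((T, 6), 0.1)
        d[:, 1] += np.linspace(0, 0.001, T)  # mild noise elsewhere
        d[30:, 5] = 2.0  # flat, stabilized, then a late jump
        flags = detect_secondary_excitation(self._effect(d), [0], onset_ms=0.0)
        row = flags[flags["node"] == 5].iloc[0]
        assert row["kind"] == "late_reexcitation"


class TestEffectSeriesFromRuns:
    def test_round_trip_through_simulation(self, toy_connectome, short_cfg, short_protocol):
        from stimnet.engine import run_paired

        stim, nostim = run_paired(toy_connectome, "healthy", short_cfg, short_protocol)
        eff = effect_series(stim, nostim)
        assert eff.D.shape == stim.times_ms.shape
        assert eff.d.shape == (stim.n_snapshots, toy_connectome.n)
        assert np.all(eff.D >= 0) and np.all(eff.d >= 0)
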