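import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stimnet.plasticity import (
    ActivitySamples,
    PlasticityConfig,
    external_weight_update,
    internal_weight_update,
    normalize_external,
    normalize_internal,
)


def make_samples(n, current_E, previous_E, delayed, Is=None, Id=None,
                 previous_Is=None, previous_Id=None):
    cur = np.stack([
        np.asarray(current_E, float),
        np.asarray(Is if Is is not None else np.zeros(n), float),
        np.asarray(Id if Id is not None else np.zeros(n), float),
    ])
    prev = np.stack([
        np.asarray(previous_E, float),
        np.asarray(previous_Is if previous_Is is not None else cur[1], float),
        np.asarray(previous_Id if previous_Id is not None else cur[2], float),
    ])
    return ActivitySamples(current=cur, previous=prev, delayed_E=np.asarray(delayed, float))


class TestExternalUpdate:
    def test_single_edge_delta(self):
        # delta = c * E_pre(t - del) * (E_post(t) - E_post(t-1))
        n = 2
        W = np.zeros((n, n))
        mask = np.array([[False, True], [True, False]])
        samples = make_samples(
            n, current_E=[0.0, 0.6], previous_E=[0.0, 0.4],
            delayed=[[0.0, 0.5], [0.0, 0.0]],
        )
        W2 = external_weight_update(W, samples, PlasticityConfig(c_external=0.1), mask)
        assert W2[0, 1] == pytest.approx(0.01, abs=1e-15)

    def test_no_postsynaptic_change_means_no_update(self, rng):
        n = 4
        W = rng.uniform(0, 1, (n, n))
        mask = np.ones((n, n), bool)
        np.fill_diagonal(mask, False)
        W *= mask
        E = rng.uniform(0, 1, n)
        samples = make_samples(n, E, E, rng.uniform(0, 1, (n, n)))
        W2 = external_weight_update(W, samples, PlasticityConfig(), mask)
        assert np.array_equal(W2, W)

    def test_zero_learning_rate(self, rng):
        n = 3
        mask = np.ones((n, n), bool)
        np.fill_diagonal(mask, False)
        W = rng.uniform(0, 1, (n, n)) * mask
        samples = make_samples(n, rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                               rng.uniform(0, 1, (n, n)))
        W2 = external_weight_update(W, samples, PlasticityConfig(c_external=0.0), mask)
        assert np.array_equal(W2, W)

    def test_learning_rate_linearity(self, rng):
        n = 5
        mask = rng.random((n, n)) < 0.6
        np.fill_diagonal(mask, False)
        W = np.full((n, n), 10.0) * mask  # large enough that clipping is inactive
        samples = make_samples(n, rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                               rng.uniform(0, 1, (n, n)))
        d1 = external_weight_update(W, samples, PlasticityConfig(c_external=0.05), mask) - W
        d2 = external_weight_update(W, samples, PlasticityConfig(c_external=0.10), mask) - W
        assert np.allclose(d2, 2 * d1, atol=1e-12)

    def test_mask_zero_pattern_preserved(self, rng):
        n = 6
        mask = rng.random((n, n)) < 0.4
        np.fill_diagonal(mask, False)
        W = rng.uniform(0, 1, (n, n)) * mask
        samples = make_samples(n, rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                               rng.uniform(0, 1, (n, n)))
        W2 = normalize_external(external_weight_update(W, samples, PlasticityConfig(), mask))
        assert np.all(W2[~mask] == 0)

    def test_negative_results_clipped(self):
        n = 2
        mask = np.array([[False, True], [True, False]])
        W = np.full((n, n), 1e-6) * mask
        samples = make_samples(n, current_E=[0.0, 0.0], previous_E=[1.0, 1.0],
                               delayed=np.ones((n, n)))
        W2 = external_weight_update(W, samples, PlasticityConfig(), mask)
        assert np.all(W2 >= 0)


class TestNormalizeExternal:
    def test_fixed_point(self):
        W = np.array([[0.0, 0.2], [1.0, 0.2]])
        W[:, 1] = [0.4, 0.6]
        assert np.allclose(normalize_external(W)[:, 1], [0.4, 0.6])

    def test_column_sums(self):
        W = np.array([[1.0], [1.0], [2.0]])
        out = normalize_external(W)
        assert np.allclose(out[:, 0], [0.25, 0.25, 0.5])

    def test_idempotent(self, rng):
        W = rng.uniform(0, 2, (6, 6))
        once = normalize_external(W)
        assert np.allclose(normalize_external(once), once, atol=1e-15)

    def test_zero_column_left_alone(self):
        W = np.array([[0.0, 1.0], [0.0, 1.0]])
        out = normalize_external(W)
        assert np.all(out[:, 0] == 0)
        assert np.allclose(out[:, 1].sum(), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(FloatingPointError):
            normalize_external(np.array([[np.nan]]))

    @settings(deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (5, 5), elements=st.floats(0.01, 100.0)))
    def test_property_columns_sum_to_one(self, W):
        out = normalize_external(W)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)


class TestInternalUpdate:
    def test_frozen_weights_bit_identical(self, rng):
        n = 3
        w = rng.uniform(0, 1, (n, 7))
        samples = make_samples(n, rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                               np.zeros((n, n)), Is=rng.uniform(0, 1, n),
                               Id=rng.uniform(0, 1, n),
                               previous_Is=rng.uniform(0, 1, n),
                               previous_Id=rng.uniform(0, 1, n))
        out = internal_weight_update(w, samples, PlasticityConfig())
        assert np.array_equal(out[:, 4], w[:, 4])  # w5
        assert np.array_equal(out[:, 6], w[:, 6])  # w7

    def test_zero_presynaptic_activity(self):
        w = np.full(7, 0.2)
        samples = make_samples(1, [0.0], [0.5], np.zeros((1, 1)),
                               Is=[0.0], Id=[0.0], previous_Is=[0.3], previous_Id=[0.3])
        out = internal_weight_update(w, samples, PlasticityConfig())
        # every plastic connection has presynaptic activity 0 at t
        assert np.array_equal(out, w)

    def test_direct_product(self):
        # w4 (pre E, post Is): delta = 0.05 * 0.5 * 0.2 = 0.005
        w = np.full(7, 0.2)
        samples = make_samples(1, [0.5], [0.5], np.zeros((1, 1)),
                               Is=[0.6], previous_Is=[0.4], Id=[0.1], previous_Id=[0.1])
        out = internal_weight_update(w, samples, PlasticityConfig(c_internal=0.05))
        assert out[3] == pytest.approx(0.2 + 0.005, abs=1e-15)

    def test_wiring_matches_brute_force(self, rng):
        """Each plastic weight uses its own (pre, post) population pair."""
        n = 2
        cur = {k: rng.uniform(0, 1, n) for k in ("E", "Is", "Id")}
        prev = {k: rng.uniform(0, 1, n) for k in ("E", "Is", "Id")}
        w = rng.uniform(0.1, 1, (n, 7))
        samples = make_samples(n, cur["E"], prev["E"], np.zeros((n, n)),
                               Is=cur["Is"], Id=cur["Id"],
                               previous_Is=prev["Is"], previous_Id=prev["Id"])
        out = internal_weight_update(w, samples, PlasticityConfig())
        wiring = {0: ("E", "E"), 1: ("Is", "E"), 2: ("Id", "E"),
                  3: ("E", "Is"), 5: ("Is", "Id")}
        c = PlasticityConfig().c_internal
        for k, (pre, post) in wiring.items():
            expect = np.maximum(w[:, k] + c * cur[pre] * (cur[post] - prev[post]), 0)
            assert np.allclose(out[:, k], expect, atol=1e-15)


class TestNormalizeInternal:
    def test_uniform_vector(self):
        assert np.allclose(normalize_internal(np.ones(7)), np.full(7, 1 / 7))

    def test_sparse_vector(self):
        w = np.array([2.0, 0, 0, 0, 0, 0, 2.0])
        assert np.allclose(normalize_internal(w), [0.5, 0, 0, 0, 0, 0, 0.5])

    def test_idempotent(self, rng):
        w = rng.uniform(0.1, 5, (4, 7))
        once = normalize_internal(w)
        assert np.allclose(normalize_internal(once), once, atol=1e-15)

    def test_zero_sum_rejected(self):
        with pytest.raises(FloatingPointError):
            normalize_internal(np.zeros(7))

    def test_frozen_scope_mode_keeps_w5_w7(self, rng):
        cfg = PlasticityConfig(renormalize_frozen=False)
        w = np.array([0.2, 0.2, 0.2, 0.2, 0.05, 0.2, 0.05])
        out = normalize_internal(w, cfg)
        assert out[4] == pytest.approx(0.05) and out[6] == pytest.approx(0.05)
        assert out.sum() == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (3, 7), elements=st.floats(0.01, 50.0)))
    def test_property_rows_sum_to_one(self, w):
        assert np.allclose(normalize_internal(w).sum(axis=1), 1.0, atol=1e-12)
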