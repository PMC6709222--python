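import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from kinetime.core_io import Trajectory
from kinetime.observer import ObserverParams, simulate_reproduction_trial
from kinetime.reproduction import (central_tendency_slope, discrete_frechet,
                                   path_similarity, reproduced_duration,
                                   reproduction_cv, resample_arclength)


def brute_force_frechet(P, Q):
    """Independent oracle: enumerate all monotone couplings recursively."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    d = np.hypot(P[:, None, 0] - Q[None, :, 0], P[:, None, 1] - Q[None, :, 1])
    n, m = d.shape
    best = [np.inf]

    def walk(i, j, cur):
        cur = max(cur, d[i, j])
        if cur >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cur
            return
        if i + 1 < n:
            walk(i + 1, j, cur)
        if j + 1 < m:
            walk(i, j + 1, cur)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cur)

    walk(0, 0, 0.0)
    return best[0]


def reproduction_traj(move_from_ms, move_to_ms, total_ms, speed=10.0):
    """Constructed reproduction-phase trajectory: still, move along x at
    ``speed`` cm/s, still."""
    v = np.zeros(total_ms)
    v[move_from_ms:move_to_ms] = speed / 1000.0
    x = np.cumsum(v)
    n = total_ms
    return Trajectory(("s", 0, 0), np.arange(n), x, np.zeros(n),
                      np.zeros(n), np.zeros(n),
                      np.array(["reproduction"] * n, object))


class TestReproducedDuration:
    def test_constructed_2000ms_movement(self):
        tj = reproduction_traj(500, 2500, 3200)
        assert reproduced_duration(tj) == pytest.approx(2000, abs=4)

    def test_simulator_ground_truth_within_10ms(self):
        rng = np.random.default_rng(0)
        p = ObserverParams(seed=1)
        for _ in range(5):
            res = simulate_reproduction_trial(1800, "hold", p, rng)
            got = reproduced_duration(res["trajectory"])
            assert got == pytest.approx(res["reproduced_ms"], abs=10)

    def test_never_moving_nan(self):
        tj = reproduction_traj(0, 0, 500)
        with pytest.warns(UserWarning):
            assert np.isnan(reproduced_duration(tj))

    def test_micro_pause_does_not_split_movement(self):
        """A 50-ms pause inside the movement is ignored; only the 200-ms
        stationary tail ends it."""
        v = np.zeros(3000)
        v[300:1300] = 0.01
        v[1350:2300] = 0.01  # 50-ms micro-pause at 1300
        x = np.cumsum(v)
        tj = Trajectory(("s", 0, 0), np.arange(3000), x, np.zeros(3000),
                        np.zeros(3000), np.zeros(3000),
                        np.array(["reproduction"] * 3000, object))
        assert reproduced_duration(tj) == pytest.approx(2000, abs=15)


class TestCentralTendency:
    def test_veridical_slope_one(self):
        x = np.array([1000, 2000, 3000, 4000], float)
        slope, intercept = central_tendency_slope(x, x)
        assert slope == pytest.approx(1.0) and intercept == pytest.approx(0.0)

    def test_constant_reproduction_slope_zero(self):
        x = np.array([1000, 2000, 3000, 4000], float)
        slope, _ = central_tendency_slope(x, np.full(4, 2500.0))
        assert slope == pytest.approx(0.0)

    def test_shrinkage_orders_slopes(self):
        """Log-domain shrinkage w=0.4 gives a slope in (0,1), below w=0.1."""
        rng = np.random.default_rng(1)
        d = np.repeat([1000, 1500, 2000, 2500, 3000, 3500, 4000], 1500)
        slopes = {}
        for w in (0.1, 0.4):
            r = np.exp((1 - w) * np.log(d) + w * np.log(2000.0)
                       + 0.1 * rng.standard_normal(len(d)))
            slopes[w], _ = central_tendency_slope(d, r)
        assert 0 < slopes[0.4] < slopes[0.1] < 1.05

    def test_constant_presented_raises(self):
        with pytest.raises(ValueError):
            central_tendency_slope([2000, 2000], [1800, 2200])


class TestReproductionCv:
    def trials(self, durations, reproduced):
        return pd.DataFrame({"duration_ms": durations, "reproduced_ms": reproduced})

    def test_all_equal_zero_cv(self):
        out = reproduction_cv(self.trials([1000] * 5, [900.0] * 5))
        assert out["cv"].iloc[0] == 0.0

    def test_lognormal_closed_form(self):
        """CV of exp(N(mu, 0.2^2)) is sqrt(exp(0.04)-1) ~ 0.202."""
        rng = np.random.default_rng(2)
        r = np.exp(np.log(2000) + 0.2 * rng.standard_normal(10_000))
        out = reproduction_cv(self.trials([2000.0] * 10_000, r))
        assert out["cv"].iloc[0] == pytest.approx(np.sqrt(np.exp(0.04) - 1), rel=0.05)

    def test_single_value_nan(self):
        out = reproduction_cv(self.trials([1000.0], [900.0]))
        assert np.isnan(out["cv"].iloc[0])


class TestDiscreteFrechet:
    @pytest.mark.parametrize("P,Q,expected", [
        ([(0, 0), (1, 0)], [(0, 0), (1, 0)], 0.0),
        ([(0, 0), (1, 0)], [(0, 1), (1, 1)], 1.0),
        ([(0, 0), (3, 0)], [(0, 1), (1, 2), (3, 1)], np.sqrt(5)),
    ])
    def test_worked_examples(self, P, Q, expected):
        assert discrete_frechet(P, Q) == pytest.approx(expected)

    def test_symmetry_and_lower_bound(self, rng):
        for _ in range(20):
            P = rng.uniform(-5, 5, (rng.integers(2, 8), 2))
            Q = rng.uniform(-5, 5, (rng.integers(2, 8), 2))
            df1 = discrete_frechet(P, Q)
            assert df1 == pytest.approx(discrete_frechet(Q, P))
            assert df1 >= max(np.linalg.norm(P[0] - Q[0]),
                              np.linalg.norm(P[-1] - Q[-1])) - 1e-12

    def test_dp_equals_brute_force_enumeration(self, rng):
        """Exhaustive coupling oracle for all polylines with <= 6 vertices."""
        for _ in range(120):
            P = rng.uniform(-3, 3, (rng.integers(1, 7), 2))
            Q = rng.uniform(-3, 3, (rng.integers(1, 7), 2))
            assert discrete_frechet(P, Q) == pytest.approx(brute_force_frechet(P, Q))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            discrete_frechet(np.empty((0, 2)), [(0, 0)])

    @given(st_.floats(-3, 3), st_.floats(-3, 3))
    @settings(max_examples=25, deadline=None)
    def test_translation_of_equal_curves(self, dx, dy):
        P = np.array([(0, 0), (1, 0.5), (2, 0)])
        Q = P + np.array([dx, dy])
        assert discrete_frechet(P, Q) == pytest.approx(np.hypot(dx, dy))


class TestPathSimilarity:
    def make_dataset(self, copy=True):
        n_enc, n_rep = 1500, 1600
        rng = np.random.default_rng(0)
        enc = np.cumsum(rng.normal(0, 0.01, (n_enc, 2)), axis=0)
        if copy:
            rep = np.vstack([enc, np.repeat(enc[-1:], n_rep - n_enc, axis=0)])
        else:
            rep = np.cumsum(rng.normal(0, 0.01, (n_rep, 2)), axis=0) + 2.0
        xy = np.vstack([enc, rep])
        n = len(xy)
        phase = np.array(["encoding"] * n_enc + ["reproduction"] * (n - n_enc), object)
        tj = Trajectory(("s", 0, 0), np.arange(n), xy[:, 0], xy[:, 1],
                        np.zeros(n), np.zeros(n), phase)
        trials = pd.DataFrame([{"subject_id": "s", "block": 0, "trial": 0,
                                "duration_ms": 1500.0, "condition": "free"}])
        return trials, [tj]

    def test_copied_path_zero(self):
        trials, trajs = self.make_dataset(copy=True)
        out = path_similarity((trials, trajs))
        assert out["frechet_cm"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_translated_path_distance(self):
        """Translating the encoding path by 2 cm gives dF = 2 on the
        resampled grid."""
        rng = np.random.default_rng(1)
        enc = np.cumsum(rng.normal(0, 0.01, (1000, 2)), axis=0)
        rep = enc + np.array([2.0, 0.0])
        p = resample_arclength(enc, 100)
        q = resample_arclength(rep, 100)
        assert discrete_frechet(p, q) == pytest.approx(2.0, abs=1e-9)

    def test_independent_paths_positive(self):
        trials, trajs = self.make_dataset(copy=False)
        out = path_similarity((trials, trajs))
        assert out["frechet_cm"].iloc[0] > 1.0
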