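import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from kinetime.core_io import Geometry, Trajectory
from kinetime.kinematics import (force_direction, intertrial_sd, normalize_readout,
                                 path_length, proximity_ratio, readout_matrix)
from kinetime.observer import ObserverParams, simulate_bisection_trial


def traj_from_xy(xy, key=("s", 0, 0), phase="tone", t0=0):
    xy = np.asarray(xy, float)
    n = len(xy)
    return Trajectory(key, np.arange(t0, t0 + n), xy[:, 0], xy[:, 1],
                      np.zeros(n), np.zeros(n), np.array([phase] * n, object))


class TestPathLength:
    def test_stationary_is_zero(self):
        tj = traj_from_xy(np.zeros((100, 2)))
        assert path_length(tj) == 0.0

    def test_345_segment(self):
        tj = traj_from_xy([(0, 0), (3, 4)])
        assert path_length(tj) == pytest.approx(5.0)

    def test_unit_square_traversal(self):
        tj = traj_from_xy([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        assert path_length(tj) == pytest.approx(4.0)

    def test_empty_window_warns_zero(self):
        tj = traj_from_xy(np.zeros((10, 2)))
        with pytest.warns(UserWarning):
            assert path_length(tj, (100, 200)) == 0.0


class TestProximityRatio:
    def test_midpoint_is_one(self, geometry):
        mid = np.add(geometry.short_target_xy, geometry.long_target_xy) / 2
        assert proximity_ratio(mid, geometry) == pytest.approx(1.0)

    def test_two_vs_eight_cm(self, geometry):
        """A point 2 cm from the short target and 8 cm from the long target
        has ratio 4 (>1 means closer to short)."""
        s = np.asarray(geometry.short_target_xy)
        l = np.asarray(geometry.long_target_xy)
        u = (l - s) / np.linalg.norm(l - s)
        point = s + 2 * u  # on the segment: 2 cm from short
        d_long = np.linalg.norm(l - point)
        assert proximity_ratio(point, geometry) == pytest.approx(d_long / 2.0)
        # construct the exact 2-vs-8 case on a synthetic geometry
        g = Geometry(short_target_xy=(0.0, 0.0), long_target_xy=(10.0, 0.0))
        assert proximity_ratio((2.0, 0.0), g) == pytest.approx(4.0)

    def test_reflection_product_is_one(self, geometry):
        rng = np.random.default_rng(0)
        s = np.asarray(geometry.short_target_xy)
        l = np.asarray(geometry.long_target_xy)
        mid = (s + l) / 2
        axis = (l - s) / np.linalg.norm(l - s)
        for _ in range(20):
            p = rng.uniform(-10, 10, 2)
            # reflect across the perpendicular bisector of the two targets
            q = p - 2 * np.dot(p - mid, axis) * axis
            assert proximity_ratio(p, geometry) * proximity_ratio(q, geometry) \
                == pytest.approx(1.0, rel=1e-9)

    def test_at_target_center_is_inf(self, geometry):
        assert np.isinf(proximity_ratio(geometry.short_target_xy, geometry))


class TestForceDirection:
    @pytest.mark.parametrize("fx,fy,deg", [(1, 0, 0.0), (0, 1, 90.0), (-1, 0, 180.0)])
    def test_cardinal_directions(self, fx, fy, deg):
        assert force_direction(fx, fy) == pytest.approx(deg)

    def test_unit_vector_at_short_target_is_105(self, geometry):
        a = np.radians(105.0)
        assert force_direction(np.cos(a), np.sin(a)) == pytest.approx(105.0)

    def test_zero_vector_nan(self):
        assert np.isnan(force_direction(0.0, 0.0))


class TestNormalizeReadout:
    def test_neutral_values_map_to_half(self, geometry):
        assert normalize_readout(1.0, "ratio") == pytest.approx(0.5)
        assert normalize_readout(90.0, "force", geometry) == pytest.approx(0.5)

    def test_force_complementarity(self, geometry):
        for x in (5.0, 12.0, 30.0):
            s1 = normalize_readout(90.0 + x, "force", geometry)
            s2 = normalize_readout(90.0 - x, "force", geometry)
            assert s1 + s2 == pytest.approx(1.0)

    def test_ratio_equals_distance_share(self):
        # ratio r = d_long/d_short -> share d_long/(d_long+d_short)
        assert normalize_readout(4.0, "ratio") == pytest.approx(0.8)

    @given(st_.floats(0.01, 100), st_.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_ratio_strictly_monotone(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert normalize_readout(lo, "ratio") < normalize_readout(hi, "ratio")

    def test_nan_propagates(self):
        assert np.isnan(normalize_readout(np.nan, "force"))


class TestIntertrialSd:
    def make(self, offsets):
        trials = pd.DataFrame({
            "subject_id": "s", "block": 0, "trial": range(len(offsets)),
            "duration_ms": 2000.0, "condition": "free"})
        trajs = [traj_from_xy(np.tile([off, 0.0], (150, 1)), key=("s", 0, i))
                 for i, off in enumerate(offsets)]
        return trajs, trials

    def test_identical_trajectories_zero(self):
        trajs, trials = self.make([1.0, 1.0, 1.0])
        out = intertrial_sd(trajs, trials)
        assert out["intertrial_sd_cm"].iloc[0] == 0.0

    def test_two_trial_offset_closed_form(self):
        """Two trials offset by dx=2: SD_x = sqrt(2) each ms, SD_y = 0, so the
        x/y-averaged output is sqrt(2)/2."""
        trajs, trials = self.make([0.0, 2.0])
        out = intertrial_sd(trajs, trials)
        assert out["intertrial_sd_cm"].iloc[0] == pytest.approx(np.sqrt(2) / 2)

    def test_single_trial_nan(self):
        trajs, trials = self.make([0.0])
        with pytest.warns(UserWarning):
            out = intertrial_sd(trajs, trials)
        assert np.isnan(out["intertrial_sd_cm"].iloc[0])

    def test_noise_inflates_sd(self):
        rng = np.random.default_rng(5)
        base = [0.0] * 40
        trajs, trials = self.make(base)
        noisy = [traj_from_xy(np.tile([0.0, 0.0], (150, 1))
                              + rng.normal(0, 0.5, (150, 2)), key=("s", 0, i))
                 for i in range(40)]
        quiet = intertrial_sd(trajs, trials)["intertrial_sd_cm"].iloc[0]
        loud = intertrial_sd(noisy, trials)["intertrial_sd_cm"].iloc[0]
        assert loud > quiet
        assert loud == pytest.approx(0.5, rel=0.2)


@pytest.fixture(scope="module")
def readout_dataset(geometry):
    rng = np.random.default_rng(2)
    p = ObserverParams(lapse=0.0)
    rows, trajs = [], []
    for i, dur in enumerate([1000, 2000, 4000] * 4):
        cond = "hold" if i % 2 else "free"
        res = simulate_bisection_trial(dur, cond, p, rng, trial_key=("s", 0, i))
        rows.append({"subject_id": "s", "block": 0, "trial": i,
                     "duration_ms": float(dur), "condition": cond,
                     "choice": res["choice"]})
        trajs.append(res["trajectory"])
    return pd.DataFrame(rows), trajs


class TestReadoutMatrix:

    def test_window_1000_step_1_gives_1000_columns(self, readout_dataset, geometry):
        trials, trajs = readout_dataset
        kept, times, mat = readout_matrix(trajs, trials, geometry)
        assert mat.shape[1] == 1000
        assert times[0] == -1000 and times[-1] == -1

    def test_alignment_against_single_trial_extraction(self, readout_dataset, geometry):
        from kinetime.kinematics import trial_readout_series
        trials, trajs = readout_dataset
        kept, times, mat = readout_matrix(trajs, trials, geometry)
        row = kept.iloc[0]
        tj = next(t for t in trajs if t.trial_key == (row.subject_id, row.block, row.trial))
        series = trial_readout_series(tj, row.condition, geometry)
        assert mat[0, -1] == pytest.approx(series[-1])       # t = -1: 1 ms before offset
        assert mat[0, 0] == pytest.approx(series[-1000])

    def test_constant_force_gives_constant_row(self, geometry):
        n = 1200
        ang = np.radians(100.0)
        tj = Trajectory(("s", 0, 0), np.arange(n), np.zeros(n), np.zeros(n),
                        np.full(n, np.cos(ang)), np.full(n, np.sin(ang)),
                        np.array(["tone"] * n, object))
        trials = pd.DataFrame([{"subject_id": "s", "block": 0, "trial": 0,
                                "duration_ms": 1200.0, "condition": "hold"}])
        _, _, mat = readout_matrix([tj], trials, geometry)
        assert np.ptp(mat[0]) < 1e-12

    def test_short_tone_excluded(self, geometry):
        tj = traj_from_xy(np.zeros((500, 2)))
        trials = pd.DataFrame([{"subject_id": "s", "block": 0, "trial": 0,
                                "duration_ms": 500.0, "condition": "free"}])
        with pytest.warns(UserWarning):
            kept, _, mat = readout_matrix([tj], trials, geometry)
        assert len(kept) == 0
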