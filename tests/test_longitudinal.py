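"""Control-ROI geometry, windowed ROI means, realignment and normalization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qmi.longitudinal import (LesionExcluded, LesionRecord, extract_series,
                              make_control_roi, realign_and_normalize,
                              roi_mean)


def brute_force_shell(mask):
    """Oracle: voxels within Chebyshev distance 1 of the lesion, minus it."""
    out = np.zeros_like(mask)
    for (i, j, k) in np.argwhere(mask):
        for di, dj, dk in itertools.product((-1, 0, 1), repeat=3):
            x, y, z = i + di, j + dj, k + dk
            if (0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                    and 0 <= z < mask.shape[2]):
                out[x, y, z] = True
    return out & ~mask


class TestControlRoi:
    def test_single_interior_voxel_gives_26_shell(self):
        m = np.zeros((7, 7, 7), dtype=bool)
        m[3, 3, 3] = True
        ctl = make_control_roi(m)
        assert ctl.sum() == 26
        assert not np.any(ctl & m)

    def test_two_voxel_lesion_gives_34_shell(self):
        # 2x1x1 lesion dilates to a 3x3x4 box: 36 - 2 = 34 control voxels
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = m[4, 4, 5] = True
        assert make_control_roi(m).sum() == 34

    def test_empty_lesion_rejected(self):
        with pytest.raises(ValueError):
            make_control_roi(np.zeros((3, 3, 3), dtype=bool))

    def test_full_volume_lesion_rejected(self):
        with pytest.raises(ValueError):
            make_control_roi(np.ones((3, 3, 3), dtype=bool))

    def test_border_lesion_truncated_with_warning(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[0, 2, 2] = True
        with pytest.warns(UserWarning, match="border"):
            ctl = make_control_roi(m)
        assert ctl.sum() == 17  # 2x3x3 box minus the lesion voxel

    def test_matches_brute_force_on_random_masks(self):
        """100 random small lesions against the enumeration oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            m = np.zeros((10, 10, 8), dtype=bool)
            n_seeds = rng.integers(1, 4)
            for _ in range(n_seeds):
                c = rng.integers(1, [9, 9, 7])
                m[c[0], c[1], c[2]] = True
                if rng.random() < 0.5:
                    m[c[0] + rng.integers(-1, 2), c[1], c[2]] = True
            np.testing.assert_array_equal(make_control_roi(m),
                                          brute_force_shell(m))

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_every_control_voxel_touches_lesion(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((8, 8, 8), dtype=bool)
        for _ in range(rng.integers(1, 5)):
            c = rng.integers(1, 7, size=3)
            m[tuple(c)] = True
        ctl = make_control_roi(m)
        assert not np.any(ctl & m)
        shell = brute_force_shell(m)
        assert np.all(ctl <= shell)  # 26-adjacency of every control voxel


class TestRoiMean:
    def test_window_worked_example(self):
        r2s = np.array([3.0, 10.0, 31.0, 15.0]).reshape(1, 1, 4)
        par = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        roi = np.ones((1, 1, 4), dtype=bool)
        mean, n = roi_mean(par, roi, r2s)
        assert (mean, n) == (3.0, 2)

    def test_all_voxels_outside_window_is_missing(self):
        r2s = np.full((1, 1, 3), 2.0)  # CSF-like
        mean, n = roi_mean(np.ones_like(r2s), np.ones_like(r2s, dtype=bool), r2s)
        assert n == 0 and np.isnan(mean)

    def test_infinite_window_is_plain_mean(self):
        rng = np.random.default_rng(0)
        par = rng.normal(size=(4, 4, 2))
        r2s = rng.uniform(-100, 100, size=par.shape)
        roi = rng.random(par.shape) > 0.5
        mean, n = roi_mean(par, roi, r2s, accept_range=(-np.inf, np.inf))
        assert n == roi.sum()
        assert mean == pytest.approx(par[roi].mean())

    def test_window_bounds_inclusive(self):
        r2s = np.array([5.0, 30.0, 4.999, 30.001]).reshape(1, 1, 4)
        par = np.ones_like(r2s)
        _, n = roi_mean(par, np.ones_like(r2s, dtype=bool), r2s)
        assert n == 2


class TestExtractSeries:
    def _maps(self, n_visits, value_fn, r2s_value=15.0, shape=(9, 9, 9)):
        out = []
        for v in range(n_visits):
            out.append({"x": value_fn(v, shape),
                        "r2star": np.full(shape, r2s_value)})
        return out

    def test_identical_rois_give_zero_diff(self):
        record = self._record()
        maps = self._maps(4, lambda v, s: np.full(s, 7.0 + v))
        diffs = extract_series(maps, record, ["x"])
        np.testing.assert_allclose(diffs["x"], 0.0, atol=1e-14)

    def test_smooth_bias_cancels(self):
        """An additive smooth bias field moves the lesion-minus-control
        difference by under 1% of the bias amplitude."""
        record = self._record()
        shape = (9, 9, 9)
        base = self._maps(2, lambda v, s: np.full(s, 5.0))
        amplitude = 10.0
        x = np.linspace(0, 1, shape[0])[:, None, None]
        y = np.linspace(0, 1, shape[1])[None, :, None]
        bias = amplitude * (0.3 + 0.5 * x + 0.2 * y)  # linear, scale >> ROI
        biased = [dict(m) for m in base]
        biased[1]["x"] = base[1]["x"] + bias
        d0 = extract_series(base, record, ["x"])["x"]
        d1 = extract_series(biased, record, ["x"])["x"]
        assert abs(d1[1] - d0[1]) <= 0.01 * amplitude

    def test_pial_exclusion_when_window_starves_lesion(self):
        record = self._record()
        maps = self._maps(3, lambda v, s: np.full(s, 1.0), r2s_value=2.0)
        with pytest.raises(LesionExcluded, match="pial"):
            extract_series(maps, record, ["x"])

    @staticmethod
    def _record():
        m = np.zeros((9, 9, 9), dtype=bool)
        m[4, 4, 4] = m[4, 5, 4] = m[5, 4, 4] = True
        return LesionRecord(lesion_mask=m, onset_visit=1)


class TestRealignAndNormalize:
    def test_worked_example(self):
        diffs = {"x": np.array([1.0, 1.2, 0.5, 2.0])}
        s = realign_and_normalize(diffs, onset_visit=2)
        np.testing.assert_allclose(s.values["x"], [-0.1, 0.1, -0.6, 0.9])
        assert list(s.offsets) == [-2, -1, 0, 1]
        assert s.stage_labels == ["pre-lesional", "pre-lesional",
                                  "lesional", "post-lesional"]

    def test_constant_series_normalizes_to_zero(self):
        s = realign_and_normalize({"x": np.full(6, 3.3)}, onset_visit=3)
        np.testing.assert_allclose(s.values["x"], 0.0, atol=1e-14)

    def test_pre_lesional_mean_is_zero(self):
        rng = np.random.default_rng(5)
        s = realign_and_normalize({"x": rng.normal(size=8)}, onset_visit=4)
        pre = s.values["x"][s.offsets < 0]
        assert pre.mean() == pytest.approx(0.0, abs=1e-14)

    def test_onset_at_first_visit_excluded(self):
        with pytest.raises(LesionExcluded, match="no pre-lesional"):
            realign_and_normalize({"x": np.ones(5)}, onset_visit=0)

    def test_onset_at_last_visit_excluded(self):
        with pytest.raises(LesionExcluded, match="no post-lesional"):
            realign_and_normalize({"x": np.ones(5)}, onset_visit=4)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        diffs = {"x": rng.normal(size=7), "y": rng.normal(size=7)}
        once = realign_and_normalize(diffs, onset_visit=3)
        twice = realign_and_normalize(
            {p: v.copy() for p, v in once.values.items()}, onset_visit=3)
        for p in diffs:
            np.testing.assert_allclose(twice.values[p], once.values[p],
                                       atol=1e-14)

    def test_stage_values_pick_adjacent_pre_and_last_post(self):
        diffs = {"x": np.array([0.5, 1.5, 3.0, 2.0, 2.5])}
        s = realign_and_normalize(diffs, onset_visit=2)
        sv = s.stage_values("x")
        assert sv["pre-lesional"] == pytest.approx(1.5 - 1.0)
        assert sv["lesional"] == pytest.approx(3.0 - 1.0)
        assert sv["post-lesional"] == pytest.approx(2.5 - 1.0)
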