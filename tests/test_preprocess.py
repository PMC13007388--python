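"""Geometric preprocessing: resampling, normalization, centering, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fiberparc import (
    Tractogram,
    bounding_box_center,
    center_of_mass,
    center_to_atlas,
    hemisphere_of,
    minmax_normalize,
    resample_streamline,
    sample_subtractogram,
)


def _polyline(rng, n=50, scale=40.0):
    steps = rng.normal(0, scale / n, size=(n - 1, 3)) + np.array([scale / n, 0, 0])
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


class TestResample:
    def test_straight_line_uniform_spacing(self):
        line = np.array([[0.0, 0, 0], [14.0, 0, 0]])
        out = resample_streamline(line, 15)
        np.testing.assert_allclose(out[:, 0], np.arange(15), atol=1e-9)
        np.testing.assert_allclose(out[:, 1:], 0)

    def test_endpoints_preserved_exactly(self, rng):
        s = _polyline(rng)
        out = resample_streamline(s, 15)
        np.testing.assert_array_equal(out[0], s[0])
        np.testing.assert_array_equal(out[-1], s[-1])

    def test_equal_arc_length_spacing_against_cumulative_oracle(self, rng):
        """Consecutive resampled points sit at equal arc-length increments
        along the *source* polyline (cumulative-arc-length oracle)."""
        s = _polyline(rng, n=50)
        out = resample_streamline(s, 15)
        seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])

        def arc_position(p):
            # distance along the polyline of a point lying on it
            best = None
            for i in range(len(s) - 1):
                d = s[i + 1] - s[i]
                L2 = d @ d
                t = np.clip((p - s[i]) @ d / L2, 0, 1)
                proj = s[i] + t * d
                err = np.linalg.norm(p - proj)
                pos = cum[i] + t * np.sqrt(L2)
                if best is None or err < best[0]:
                    best = (err, pos)
            assert best[0] < 1e-8  # the point really lies on the polyline
            return best[1]

        positions = np.array([arc_position(p) for p in out])
        np.testing.assert_allclose(np.diff(positions), cum[-1] / 14, atol=1e-6)

    def test_idempotent_at_same_n(self):
        """Exact idempotence on a constant-curvature curve (helix): the
        first pass yields equal chords, so a second pass is the identity."""
        u = np.linspace(0, 4 * np.pi, 400)
        helix = np.column_stack([30 * np.cos(u), 30 * np.sin(u), 5 * u])
        s = resample_streamline(helix, 15)
        again = resample_streamline(s, 15)
        np.testing.assert_allclose(again, s, atol=1e-6)

    def test_zero_length_streamline_is_an_error(self):
        with pytest.raises(ValueError):
            resample_streamline(np.ones((4, 3)), 15)


class TestMinMaxNormalize:
    def test_extremes_and_midpoint(self):
        pts = np.array([[0.0, -5, 2], [10.0, 5, 4], [5.0, 0, 3]])
        out, rec = minmax_normalize(pts)
        np.testing.assert_allclose(out[0], [-1, -1, -1])
        np.testing.assert_allclose(out[1], [1, 1, 1])
        np.testing.assert_allclose(out[2], [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(rec.invert(out), pts)

    def test_idempotent(self, rng):
        pts = rng.uniform(-30, 50, size=(40, 3))
        once, _ = minmax_normalize(pts)
        twice, _ = minmax_normalize(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        pts=arrays(np.float64, (12, 3), elements=st.floats(-100, 100)),
        shift=arrays(np.float64, (3,), elements=st.floats(-50, 50)),
        scale=arrays(np.float64, (3,), elements=st.floats(0.1, 10)),
    )
    def test_invariant_to_per_axis_positive_affine(self, pts, shift, scale):
        spans = pts.max(axis=0) - pts.min(axis=0)
        if np.any(spans < 1e-6):
            return  # degenerate axis: out of contract
        a, _ = minmax_normalize(pts)
        b, _ = minmax_normalize(pts * scale + shift)
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_degenerate_axis_is_an_error(self):
        pts = np.array([[0.0, 1, 2], [1.0, 1, 3]])  # y axis has zero span
        with pytest.raises(ValueError):
            minmax_normalize(pts)


class TestCentering:
    def test_bounding_box_center_midpoint(self):
        pts = np.array([[-10.0, -20, -5], [30.0, 20, 15], [3.0, 1, 2]])
        t = Tractogram(streamlines=[pts])
        np.testing.assert_allclose(bounding_box_center(t), [10, 0, 5])

    def test_symmetric_tractogram_centers_at_origin(self):
        pts = np.array([[-7.0, -3, -2], [7.0, 3, 2]])
        t = Tractogram(streamlines=[pts])
        np.testing.assert_allclose(bounding_box_center(t), 0, atol=1e-12)
        np.testing.assert_allclose(center_of_mass(t), 0, atol=1e-12)

    def test_against_brute_force_oracles(self, rng):
        sl = [rng.uniform(-50, 50, size=(rng.integers(3, 20), 3))
              for _ in range(40)]
        t = Tractogram(streamlines=sl)
        flat = np.concatenate([s for s in sl])
        np.testing.assert_allclose(
            bounding_box_center(t), (flat.min(0) + flat.max(0)) / 2)
        np.testing.assert_allclose(center_of_mass(t), flat.mean(0))

    def test_duplication_moves_com_but_not_bbox(self, rng):
        """Density asymmetry biases the center of mass, never the bounding box."""
        sl = [rng.uniform(-50, 50, size=(10, 3)) for _ in range(10)]
        right = [s + np.array([40.0, 0, 0]) for s in sl[:2]]
        t = Tractogram(streamlines=sl + right)
        dup = Tractogram(streamlines=sl + right * 9)
        np.testing.assert_allclose(
            bounding_box_center(dup), bounding_box_center(t), atol=1e-12)
        assert center_of_mass(dup)[0] > center_of_mass(t)[0]

    def test_center_to_atlas_formula_and_idempotence(self, rng):
        sl = [rng.uniform(0, 30, size=(8, 3)) + np.array([10.0, 0, 5])
              for _ in range(5)]
        t = Tractogram(streamlines=sl)
        c_atlas = np.array([1.0, -2.0, 3.0])
        out = center_to_atlas(t, c_atlas, strategy="bbox")
        shift = c_atlas - bounding_box_center(t)
        for a, b in zip(out.streamlines, t.streamlines):
            np.testing.assert_allclose(a, b + shift)
        np.testing.assert_allclose(bounding_box_center(out), c_atlas, atol=1e-9)
        again = center_to_atlas(out, c_atlas, strategy="bbox")
        for a, b in zip(again.streamlines, out.streamlines):
            np.testing.assert_allclose(a, b, atol=1e-9)


class TestHemisphere:
    @pytest.mark.parametrize(
        "mean_x,expected",
        [(-3.2, "left"), (0.0, "right"), (0.4, "right")],
    )
    def test_centroid_rule(self, mean_x, expected):
        pts = np.array([[mean_x - 1, 0, 0], [mean_x + 1, 5, 5]])
        assert hemisphere_of(pts) == expected

    def test_midline_crossing_streamline_uses_mean(self):
        pts = np.array([[-2.0, 0, 0], [0.0, 0, 0], [3.2, 0, 0]])  # mean 0.4
        assert hemisphere_of(pts) == "right"


class TestSampleSubtractogram:
    @pytest.fixture
    def lateralized(self, rng):
        left = [rng.normal([-20, 0, 0], 2, size=(15, 3)) for _ in range(60)]
        right = [rng.normal([20, 0, 0], 2, size=(15, 3)) for _ in range(60)]
        labels = np.array([0] * 60 + [1] * 60)
        return Tractogram(streamlines=left + right, labels=labels)

    def test_size_bounds_and_labels(self, lateralized, rng):
        sub = sample_subtractogram(lateralized, 50, rng=rng)
        assert sub.streamlines.shape == (50, 15, 3)
        assert np.all(sub.streamlines >= -1) and np.all(sub.streamlines <= 1)
        assert sub.labels.shape == (50,)

    def test_unilateral_restricts_pool(self, lateralized, rng):
        sub = sample_subtractogram(lateralized, 40, unilateral="left", rng=rng)
        assert np.all(sub.labels == 0)
        assert sub.unilateral == "left"

    def test_unilateral_empty_pool_names_side(self, rng):
        right_only = Tractogram(
            streamlines=[rng.normal([20, 0, 0], 1, size=(15, 3))
                         for _ in range(5)]
        )
        with pytest.raises(ValueError, match="left"):
            sample_subtractogram(right_only, 3, unilateral="left", rng=rng)

    def test_same_seed_identical(self, lateralized):
        a = sample_subtractogram(lateralized, 30,
                                 rng=np.random.default_rng(5))
        b = sample_subtractogram(lateralized, 30,
                                 rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.streamlines, b.streamlines)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_small_pool_sampled_with_replacement(self, rng):
        t = Tractogram(streamlines=[rng.uniform(-5, 5, (15, 3))
                                    for _ in range(4)])
        sub = sample_subtractogram(t, 10, rng=rng)
        assert sub.context_size == 10
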