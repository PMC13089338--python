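import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mesoquant import (
    CalibratedImage,
    MaskImage,
    SceneConfig,
    TrajectoryConfig,
    build_trajectory,
    compare_groups,
    detect_leakage_onset,
    estimate_volume,
    fit_bounding_box,
    make_body_scene,
    make_trajectory,
    segment_body,
)


def disk_mask(radius_um: float, pixel_size: float = 1.0) -> MaskImage:
    n = int(2 * radius_um / pixel_size) + 9
    y, x = (np.mgrid[0:n, 0:n] - (n - 1) / 2.0) * pixel_size
    return MaskImage(np.hypot(x, y) <= radius_um, pixel_size)


def ellipse_mask(a_um, b_um, angle_deg, pixel_size=1.0) -> MaskImage:
    n = int(2 * max(a_um, b_um) / pixel_size) + 9
    y, x = (np.mgrid[0:n, 0:n] - (n - 1) / 2.0) * pixel_size
    t = math.radians(angle_deg)
    xr = x * math.cos(t) + y * math.sin(t)
    yr = -x * math.sin(t) + y * math.cos(t)
    return MaskImage((xr / a_um) ** 2 + (yr / b_um) ** 2 <= 1.0, pixel_size)


def calipers_ar(mask: MaskImage, n_angles: int = 720) -> float:
    """Brute-force oracle: minimal-area enclosing rectangle over a fine
    angle sweep of the boundary pixels; returns its long/short ratio."""
    from skimage.segmentation import find_boundaries

    rows, cols = np.nonzero(find_boundaries(mask.pixels, mode="inner"))
    pts = np.column_stack([cols, rows]).astype(float) * mask.pixel_size
    best = None
    for ang in np.linspace(0, np.pi / 2, n_angles, endpoint=False):
        c, s = math.cos(ang), math.sin(ang)
        u = pts[:, 0] * c + pts[:, 1] * s
        v = -pts[:, 0] * s + pts[:, 1] * c
        du = u.max() - u.min() + mask.pixel_size
        dv = v.max() - v.min() + mask.pixel_size
        if best is None or du * dv < best[0]:
            best = (du * dv, max(du, dv) / min(du, dv))
    return best[1]


class TestSegmentBody:
    def test_recovers_truth_mask(self):
        channels, truth_mask, _ = make_body_scene(SceneConfig(seed=0))
        mask = segment_body(channels["ColIV"])
        inter = (mask.pixels & truth_mask.pixels).sum()
        union = (mask.pixels | truth_mask.pixels).sum()
        assert inter / union >= 0.98

    def test_empty_foreground_error(self):
        img = CalibratedImage(np.ones((10, 10)), 1.0)
        with pytest.raises(ValueError):
            segment_body(img, threshold=5.0)
        with pytest.raises(ValueError):
            segment_body(img, threshold="auto")  # constant image

    def test_largest_component_retained(self):
        px = np.zeros((60, 60))
        px[5:30, 5:25] = 10.0  # 500 px
        px[40:50, 40:45] = 10.0  # 50 px
        mask = segment_body(CalibratedImage(px, 1.0), threshold=5.0)
        assert mask.pixels[10, 10] and not mask.pixels[45, 42]


class TestFitBoundingBox:
    def test_axis_aligned_rectangle(self):
        px = np.zeros((120, 40), dtype=bool)
        px[10:110, 10:35] = True
        shape = fit_bounding_box(MaskImage(px, 1.0))
        assert shape.l == pytest.approx(100.0, rel=0.01)
        assert shape.w == pytest.approx(25.0, rel=0.01)
        assert shape.ar == pytest.approx(4.0, rel=0.02)

    def test_disk_is_isotropic(self):
        shape = fit_bounding_box(disk_mask(30.0))
        assert shape.ar == pytest.approx(1.0, abs=0.02)

    def test_rotated_ellipse_vs_calipers_oracle(self):
        mask = ellipse_mask(80.0, 20.0, 30.0)
        shape = fit_bounding_box(mask)
        assert shape.ar == pytest.approx(4.0, rel=0.02)
        assert shape.ar == pytest.approx(calipers_ar(mask), rel=0.02)

    def test_rotation_invariance(self):
        ars = [fit_bounding_box(ellipse_mask(60, 20, ang)).ar for ang in (0, 17, 45, 71)]
        assert max(ars) / min(ars) < 1.02

    def test_single_pixel_mask_rejected(self):
        px = np.zeros((10, 10), dtype=bool)
        px[5, 5] = True
        with pytest.raises(ValueError):
            fit_bounding_box(MaskImage(px, 1.0))


class TestEstimateVolume:
    def test_cylinder_closed_form(self):
        px = np.zeros((30, 110), dtype=bool)
        px[5:25, 5:105] = True  # 100 x 20 um rectangle -> cylinder r=10
        v = estimate_volume(MaskImage(px, 1.0))
        assert v == pytest.approx(math.pi * 100 * 100, rel=0.03)

    def test_sphere_closed_form(self):
        v = estimate_volume(disk_mask(50.0))
        assert v == pytest.approx(4.0 / 3.0 * math.pi * 50.0**3, rel=0.03)

    def test_stadium_decomposition(self):
        cfg = SceneConfig(patch_length=100.0, patch_width=20.0, pixel_size=0.5)
        from mesoquant import make_patch_scene

        mask, _ = make_patch_scene(cfg)
        expected = math.pi * 10**2 * 80 + 4.0 / 3.0 * math.pi * 10**3
        assert estimate_volume(mask) == pytest.approx(expected, rel=0.03)

    @given(scale=st.floats(0.5, 4.0))
    @settings(max_examples=20, deadline=None)
    def test_cubic_scaling(self, scale):
        px = np.zeros((30, 80), dtype=bool)
        px[7:23, 5:75] = True
        v1 = estimate_volume(MaskImage(px, 1.0))
        v2 = estimate_volume(MaskImage(px, scale))
        assert v2 == pytest.approx(v1 * scale**3, rel=1e-9)

    def test_body_scene_volume_matches_revolved_ellipsoid(self):
        channels, mask, truth = make_body_scene(SceneConfig(seed=0))
        assert estimate_volume(mask) == pytest.approx(truth.volume, rel=0.03)


class TestTrajectory:
    def test_monotone_trace_has_no_events(self):
        df, _ = make_trajectory(TrajectoryConfig(noise_cv=0.0))
        traj = build_trajectory(df)
        assert detect_leakage_onset(traj) == []

    def test_noiseless_single_drop(self):
        df, _ = make_trajectory(
            TrajectoryConfig(leakage_frame=50, leakage_fraction=0.2,
                             noise_cv=0.0, growth_rate=0.0)
        )
        events = detect_leakage_onset(build_trajectory(df))
        assert len(events) == 1
        assert events[0].frame == 50
        assert events[0].volume_drop_fraction == pytest.approx(0.2)
        assert events[0].ar_at_onset == pytest.approx(df["aspect_ratio"][50])

    def test_smoothing_window_one_is_identity(self):
        df, _ = make_trajectory(TrajectoryConfig(noise_cv=0.05, seed=1))
        traj = build_trajectory(df, smooth_window=1)
        assert np.array_equal(traj.volume_smoothed, df["volume"].to_numpy())

    def test_duplicate_timestamps_rejected(self):
        df, _ = make_trajectory(TrajectoryConfig(n_frames=5))
        df.loc[2, "time"] = df.loc[1, "time"]
        with pytest.raises(ValueError):
            build_trajectory(df)

    def test_detection_power_and_specificity(self):
        """15% drops at frame 50 under 1% CV noise: onset at 50 +/- 1 in
        >= 95% of 50 runs, and no false positives on matched no-drop traces."""
        hits = fp = 0
        for seed in range(50):
            df, _ = make_trajectory(
                TrajectoryConfig(leakage_frame=50, leakage_fraction=0.15,
                                 noise_cv=0.01, seed=seed)
            )
            ev = detect_leakage_onset(build_trajectory(df))
            hits += bool(ev) and abs(ev[0].frame - 50) <= 1
            df0, _ = make_trajectory(TrajectoryConfig(noise_cv=0.01, seed=seed))
            fp += bool(detect_leakage_onset(build_trajectory(df0)))
        assert hits >= 48  # 95% of 50
        assert fp == 0

    def test_recovery_allows_second_event(self):
        v = np.concatenate([
            np.full(10, 100.0), np.full(10, 70.0),  # first drop
            np.full(10, 120.0), np.full(10, 80.0),  # recovery, second drop
        ])
        import pandas as pd

        df = pd.DataFrame({"time": np.arange(40.0), "volume": v,
                           "aspect_ratio": np.ones(40)})
        events = detect_leakage_onset(build_trajectory(df, smooth_window=1))
        assert [e.frame for e in events] == [10, 30]


def enumeration_p(a, b):
    """Independent oracle: two-sided rank-sum p over all reassignments,
    built directly from rank sums without any shared helper."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    obs = ranks[:n_a].sum()
    mu = ranks.sum() * n_a / len(pooled)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        s = ranks[list(combo)].sum()
        count += abs(s - mu) >= abs(obs - mu) - 1e-12
        total += 1
    return count / total


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        assert compare_groups([1, 2, 3], [1, 2, 3])[1] == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        # the two most extreme of C(6,3)=20 orderings
        assert compare_groups([1, 2, 3], [10, 11, 12])[1] == pytest.approx(0.1)

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 4), (5, 5), (6, 6), (2, 10)])
    def test_exact_path_matches_enumeration(self, n_a, n_b, rng):
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.8, 1, n_b)
        _, p = compare_groups(a, b)
        assert p == pytest.approx(enumeration_p(a, b))

    def test_exact_path_matches_scipy_exact_tie_free(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(1, 1, 6)
        _, p = compare_groups(a, b)
        assert p == pytest.approx(stats.mannwhitneyu(a, b, method="exact").pvalue)

    def test_asymptotic_close_to_permutation(self, rng):
        """Approximation within 10% of a large permutation estimate for the
        thickness-comparison group sizes (12 vs 6)."""
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 6)
        _, p = compare_groups(a, b, exact_limit=12)
        perm = stats.permutation_test(
            (a, b),
            lambda x, y, axis=-1: stats.mannwhitneyu(x, y, axis=axis).statistic,
            permutation_type="independent",
            n_resamples=10**5,
            alternative="two-sided",
            rng=1,
        )
        assert p == pytest.approx(perm.pvalue, rel=0.10)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
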