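"""Shape descriptors, neck detection, positional features, feature table."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist

from mitodyn import (
    FEATURE_NAMES,
    LabelFrame,
    RunConfig,
    SceneParams,
    ScheduledEvent,
    basic_shape_features,
    classify_events,
    feature_table,
    generate_movie,
    generate_shape,
    neck_features,
    positional_features,
    region_features,
    trace_boundary,
)


def embed(mask, pad=3):
    return np.pad(np.asarray(mask, dtype=bool), pad)


class TestBasicShapeFeatures:
    def test_solid_square(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        f = basic_shape_features(mask, 0.1)
        assert f["area_um2"] == pytest.approx(1.0)
        assert f["extent"] == 1.0
        assert f["solidity"] == 1.0
        assert f["eccentricity"] == 0.0
        assert f["euler_number"] == 1
        # boundary polygon of a 10x10 square: 36 unit steps
        assert f["perimeter_um"] == pytest.approx(3.6)

    def test_euler_number_counts_holes(self):
        assert basic_shape_features(embed(generate_shape("disk", 15)), 0.1)["euler_number"] == 1
        assert basic_shape_features(embed(generate_shape("annulus", 15)), 0.1)["euler_number"] == 0
        two_holes = np.ones((9, 17), dtype=bool)
        two_holes[4, 4] = False
        two_holes[4, 12] = False
        assert basic_shape_features(embed(two_holes), 0.1)["euler_number"] == -1

    def test_l_shape_solidity_against_hull_oracle(self):
        # L-triomino of unit squares scaled x8, hull computed independently
        mask = np.zeros((16, 16), dtype=bool)
        mask[:, :8] = True
        mask[8:, :] = True
        padded = embed(mask)
        f = basic_shape_features(padded, 0.1)
        # brute-force oracle: hull over pixel-center vertices, count
        # pixel centers inside (or on) the hull
        pts = np.argwhere(padded).astype(float)
        eqs = ConvexHull(pts).equations
        grid = np.argwhere(np.ones(padded.shape, dtype=bool)).astype(float)
        inside = np.all(grid @ eqs[:, :2].T + eqs[:, 2] <= 1e-9, axis=1)
        oracle = len(pts) / inside.sum()
        assert f["solidity"] == pytest.approx(oracle, rel=0.02)

    def test_errors(self):
        with pytest.raises(ValueError):
            basic_shape_features(np.zeros((5, 5), dtype=bool), 0.1)
        two = np.zeros((8, 8), dtype=bool)
        two[1, 1] = True
        two[6, 6] = True
        with pytest.raises(ValueError):
            basic_shape_features(two, 0.1)


class TestTraceBoundary:
    def test_closed_moore_contour(self):
        mask = embed(generate_shape("disk", 15))
        contour = trace_boundary(mask)
        steps = np.diff(np.vstack([contour, contour[:1]]), axis=0)
        assert np.abs(steps).max() == 1  # consecutive pixels are Moore neighbors
        assert {tuple(p) for p in contour} <= {tuple(p) for p in np.argwhere(mask)}

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        assert trace_boundary(mask).tolist() == [[2, 3]]


class TestNeckFeatures:
    def test_straight_bar_has_no_necks(self):
        n, width = neck_features(embed(generate_shape("bar", 24)), 0.1)
        assert n == 0
        assert math.isnan(width)

    def test_disk_and_annulus_have_no_necks(self):
        assert neck_features(embed(generate_shape("disk", 21)), 0.1)[0] == 0
        assert neck_features(embed(generate_shape("annulus", 21)), 0.1)[0] == 0

    def test_dumbbell_single_neck_width(self):
        mask = embed(generate_shape("two_blob_dumbbell", 24, bridge_px=3))
        n, width = neck_features(mask, 0.1)
        assert n == 1
        # 3-px bridge: 0.3 um within one pixel (0.1 um)
        assert width == pytest.approx(0.3, abs=0.1)

    def test_dumbbell_width_matches_brute_force_minimum(self):
        # independent oracle: global minimum cross-boundary distance over
        # all ordered-boundary pairs with the same arc exclusion
        config = RunConfig()
        mask = embed(generate_shape("two_blob_dumbbell", 24, bridge_px=3))
        contour = trace_boundary(mask)
        m = len(contour)
        dist = cdist(contour, contour)
        best = np.inf
        for p in range(m):
            for q in range(p + 1, m):
                arc = min(q - p, m - (q - p))
                if arc >= 3 * config.neck_kernel_px:
                    best = min(best, dist[p, q])
        _, width = neck_features(mask, 1.0)
        assert width == pytest.approx(best, abs=1.0)

    def test_y_branch_has_a_neck(self):
        n, width = neck_features(embed(generate_shape("Y_branch", 24)), 0.1)
        assert n >= 1
        assert width > 0

    def test_small_region_returns_none(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        n, width = neck_features(mask, 0.1)
        assert n == 0 and math.isnan(width)


class TestPositionalFeatures:
    def test_two_squares_gap_distance(self):
        lab = np.zeros((30, 40), dtype=np.int32)
        lab[10:20, 5:15] = 1
        lab[10:20, 18:28] = 2  # 3 background columns between
        frame = LabelFrame(lab, 0.2)
        f = positional_features(1, frame, nucleus_centroid=None)
        assert f["nn_distance_um"] == pytest.approx(0.6)
        assert f["neighbor_surface_um"] > 0
        assert math.isnan(f["orientation_deg"])

    def test_lone_region_missing_values(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:10, 5:10] = 1
        f = positional_features(1, LabelFrame(lab, 0.1), (0.0, 0.0))
        assert math.isnan(f["nn_distance_um"])
        assert math.isnan(f["neighbor_surface_um"])
        assert not math.isnan(f["orientation_deg"])

    def test_neighbor_surface_counts_only_within_radius(self):
        lab = np.zeros((40, 200), dtype=np.int32)
        lab[18:22, 2:12] = 1
        lab[18:22, 20:30] = 2    # within 10 um of region 1 at 0.5 um/px? gap 8 px = 4 um: yes
        lab[18:22, 180:190] = 3  # gap 168 px = 84 um: far outside
        frame = LabelFrame(lab, 0.5)
        near_only = positional_features(1, frame, None)["neighbor_surface_um"]
        lab2 = lab.copy()
        lab2[lab2 == 3] = 0
        same = positional_features(1, LabelFrame(lab2, 0.5), None)["neighbor_surface_um"]
        assert near_only == pytest.approx(same)

    def test_orientation_radial_and_tangential(self):
        lab = np.zeros((21, 41), dtype=np.int32)
        lab[9:12, 5:35] = 1  # horizontal bar, centroid ~ (10, 19.5)
        frame = LabelFrame(lab, 0.1)
        # nucleus on the bar's axis: radial alignment, 0 degrees
        aligned = positional_features(1, frame, (10.0, -50.0))["orientation_deg"]
        assert aligned == pytest.approx(0.0, abs=1.0)
        # nucleus perpendicular to the axis: 90 degrees
        perp = positional_features(1, frame, (-50.0, 19.5))["orientation_deg"]
        assert perp == pytest.approx(90.0, abs=1.0)

    def test_missing_region_raises(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:5, 2:5] = 1
        with pytest.raises(KeyError):
            positional_features(7, LabelFrame(lab, 0.1), None)


class TestInvariances:
    shapes = ["disk", "bar", "L_shape", "Y_branch", "two_blob_dumbbell"]

    @pytest.mark.parametrize("kind", shapes)
    def test_scale_equivariance(self, kind):
        lab = np.zeros((80, 120), dtype=np.int32)
        mask = generate_shape(kind, 21)
        lab[5 : 5 + mask.shape[0], 5 : 5 + mask.shape[1]] = mask
        lab[60:70, 80:95] = 2  # a neighbor so positional features exist
        nucleus = (40.0, -30.0)
        f1 = region_features(1, LabelFrame(lab, 0.1), nucleus)
        # the neighborhood radius is physical (um): doubling the pixel
        # size must double it for the same pixels to count as neighbors
        config2 = RunConfig(neighbor_radius_um=20.0)
        f2 = region_features(1, LabelFrame(lab, 0.2), nucleus, config2)
        assert f2["area_um2"] == pytest.approx(4 * f1["area_um2"])
        for name in ("perimeter_um", "min_neck_width_um", "nn_distance_um", "neighbor_surface_um"):
            if not math.isnan(f1[name]):
                assert f2[name] == pytest.approx(2 * f1[name])
        for name in ("extent", "solidity", "eccentricity", "euler_number", "n_necks", "orientation_deg"):
            assert f2[name] == pytest.approx(f1[name])

    @pytest.mark.parametrize("kind", shapes)
    def test_rotation_90_invariance(self, kind):
        lab = np.zeros((90, 90), dtype=np.int32)
        mask = generate_shape(kind, 21)
        lab[5 : 5 + mask.shape[0], 5 : 5 + mask.shape[1]] = mask
        lab[70:80, 60:72] = 2
        nucleus = (45.0, -20.0)
        f1 = region_features(1, LabelFrame(lab, 0.1), nucleus)
        rot = np.rot90(lab).copy()
        h = lab.shape[1]
        nucleus_rot = (h - 1 - nucleus[1], nucleus[0])
        f2 = region_features(1, LabelFrame(rot, 0.1), nucleus_rot)
        for name in FEATURE_NAMES:
            if name == "orientation_deg" and f1["eccentricity"] < 1e-6:
                continue  # isotropic region: major axis undefined
            if math.isnan(f1[name]):
                assert math.isnan(f2[name])
            else:
                assert f2[name] == pytest.approx(f1[name], abs=1e-8), name


class TestFeatureTable:
    def test_no_confirmed_events_gives_empty_table(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:10, 5:10] = 1
        stack = [LabelFrame(lab, 0.1)] * 4
        events, _ = classify_events(stack)
        table = feature_table(events, stack)
        assert len(table) == 0
        assert list(table.columns) == ["frame", "region_id", "call"] + FEATURE_NAMES

    def test_eleven_features_per_confirmed_event(self):
        events_sched = (
            ScheduledEvent(3, "fission", (1,)),
            ScheduledEvent(5, "fusion", (2, 3)),
        )
        params = SceneParams(shape=(160, 160), n_frames=12, n_objects=5,
                             events=events_sched, nucleus_centroid=(80.0, -40.0))
        scene = generate_movie(params, seed=4)
        events, _ = classify_events(scene.truth_labels)
        table = feature_table(events, scene.truth_labels, scene.movie)
        confirmed = [e for e in events if e.call in ("fission", "fusion")]
        assert len(table) == len(confirmed) == 3  # 1 fission + 2 fusion partners
        assert len(FEATURE_NAMES) == 11
        assert not table[FEATURE_NAMES].drop(columns=["min_neck_width_um"]).isna().any().any()
        # area of the measured pre-event region matches the truth mask
        for _, row in table.iterrows():
            truth_area = (scene.truth_labels[int(row["frame"])].labels == row["region_id"]).sum()
            assert row["area_um2"] == pytest.approx(truth_area * 0.1**2)

    def test_event_referencing_missing_region_raises(self):
        from mitodyn import EventRecord

        lab = np.zeros((20, 20), dtype=np.int32)
        lab[5:10, 5:10] = 1
        stack = [LabelFrame(lab, 0.1)] * 3
        bogus = EventRecord(0, 9, 2.0, 2.0, "fission", 25)
        with pytest.raises(KeyError):
            feature_table([bogus], stack)
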