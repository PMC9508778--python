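import numpy as np
import pytest

from gazepheno import coding
from gazepheno.aoi import COARSE_OF_FINE, Box, FrameAOIMap, build_frame_aoi_map
from gazepheno.core import GazeRecording, PipelineConfig, ScreenGeometry


def _rec(t, x, y, valid, rate=300.0):
    return GazeRecording("p", "Ep", rate, np.asarray(t, float),
                         np.asarray(x, float), np.asarray(y, float),
                         np.asarray(valid, bool))


class TestDownsampling:
    def test_frame_mean_is_arithmetic_mean(self, config):
        rec = _rec([0.01, 0.02], [10, 20], [5, 5], [1, 1])
        fg = coding.downsample_to_frames(rec, 24.0, 1, config)
        assert fg.x[0] == 15.0 and fg.y[0] == 5.0
        assert fg.status[0] == coding.ON_SCREEN

    def test_all_invalid_frame_is_missing(self, config):
        rec = _rec([0.01, 0.02], [10, 20], [5, 5], [0, 0])
        fg = coding.downsample_to_frames(rec, 24.0, 1, config)
        assert fg.status[0] == coding.MISSING
        assert np.isnan(fg.x[0])

    def test_offscreen_mean_flagged(self, config):
        rec = _rec([0.01], [-50.0], [5.0], [1])
        fg = coding.downsample_to_frames(rec, 24.0, 1, config)
        assert fg.status[0] == coding.OFF_SCREEN

    def test_boundary_sample_belongs_to_later_frame(self, config):
        dt = 1 / 24.0
        rec = _rec([dt], [10], [5], [1])
        fg = coding.downsample_to_frames(rec, 24.0, 2, config)
        assert fg.status[0] == coding.MISSING
        assert fg.status[1] == coding.ON_SCREEN

    def test_rate_agnostic_300_vs_120(self, config):
        """A constant-per-frame trajectory yields identical frame means at
        300 Hz and 120 Hz sampling."""
        n_frames, fps = 48, 24.0
        frame_x = 100 + 10 * np.arange(n_frames, dtype=float)
        recs = {}
        for rate in (300.0, 120.0):
            t = (np.arange(int(n_frames / fps * rate)) + 0.5) / rate
            fidx = np.floor(t * fps).astype(int)
            recs[rate] = _rec(t, frame_x[fidx], np.full(len(t), 50.0),
                              np.ones(len(t)), rate=rate)
        fg300 = coding.downsample_to_frames(recs[300.0], fps, n_frames, config)
        fg120 = coding.downsample_to_frames(recs[120.0], fps, n_frames, config)
        np.testing.assert_allclose(fg300.x, fg120.x, atol=1e-9)
        np.testing.assert_array_equal(fg300.status, fg120.status)

    def test_nonpositive_frame_count_rejected(self, config):
        with pytest.raises(ValueError):
            coding.downsample_to_frames(_rec([0.1], [1], [1], [1]), 24.0, 0,
                                        config)


def _face_map():
    # face (100,50)-(260,250); eyes (120,70)-(240,140); mouth (120,140)-(240,230)
    return FrameAOIMap(frame=0, face_boxes=[Box(100, 50, 260, 250)],
                       eyes_boxes=[Box(120, 70, 240, 140)],
                       mouth_boxes=[Box(120, 140, 240, 230)])


class TestDiskAssignment:
    def test_disk_inside_face_away_from_parts(self, config):
        a = coding.assign_frame_aoi(0, 250.0, 240.0, _face_map(), config)
        assert (a.coarse, a.fine) == ("face", "other_face")

    def test_majority_eyes_over_mouth(self, config):
        # centre slightly above the eyes/mouth split -> more eyes pixels
        a = coding.assign_frame_aoi(0, 180.0, 135.0, _face_map(), config)
        assert (a.coarse, a.fine) == ("face", "eyes")
        assert a.overlap_px["eyes"] > a.overlap_px["mouth"]

    def test_person_free_area_nonsocial(self, config):
        a = coding.assign_frame_aoi(0, 1000.0, 800.0, _face_map(), config)
        assert (a.coarse, a.fine) == ("non_social", "n/a")

    def test_requires_onscreen_point(self, config):
        with pytest.raises(ValueError):
            coding.assign_frame_aoi(0, np.nan, 10.0, _face_map(), config)
        with pytest.raises(ValueError):
            coding.assign_frame_aoi(0, -5.0, 10.0, _face_map(), config)


def _oracle_assign(x, y, amap, config):
    """Brute-force pixel enumeration of disk overlap, from box tests only."""
    r = config.disk_radius_px
    counts = dict.fromkeys(range(6), 0)
    for iy in range(int(np.floor(y - r)) - 1, int(np.ceil(y + r)) + 2):
        for ix in range(int(np.floor(x - r)) - 1, int(np.ceil(x + r)) + 2):
            if not (0 <= ix < config.screen.width_px
                    and 0 <= iy < config.screen.height_px):
                continue
            if (ix - x) ** 2 + (iy - y) ** 2 > r * r:
                continue
            counts[amap.label_point(ix, iy)] += 1
    coarse = {"non_social": counts[0], "other_body": counts[1],
              "hands": counts[2], "face": counts[3] + counts[4] + counts[5]}
    best = max(coarse.values())
    for name in ("face", "hands", "other_body", "non_social"):
        if coarse[name] == best:
            winner = name
            break
    fine = "n/a"
    if winner == "face":
        fine_counts = {"eyes": counts[4], "mouth": counts[5],
                       "other_face": counts[3]}
        fb = max(fine_counts.values())
        for name in ("eyes", "mouth", "other_face"):
            if fine_counts[name] == fb:
                fine = name
                break
    return winner, fine, coarse


class TestOracleAgreement:
    def test_disk_assignment_matches_pixel_enumeration(self, small_config):
        """Fast patch-based assignment equals brute-force enumeration
        exactly (labels and overlap areas) on random frames."""
        rng = np.random.default_rng(7)
        screen = small_config.screen
        for _ in range(60):
            persons = []
            for _ in range(rng.integers(0, 3)):
                w, h = rng.uniform(40, 120, 2)
                x0 = rng.uniform(-20, screen.width_px - w / 2)
                y0 = rng.uniform(-20, screen.height_px - h / 2)
                kp = {"left_eye": [x0 + 0.3 * w, y0 + 0.4 * h],
                      "right_eye": [x0 + 0.7 * w, y0 + 0.4 * h],
                      "nose": [x0 + 0.5 * w, y0 + 0.55 * h],
                      "mouth_left": [x0 + 0.3 * w, y0 + 0.72 * h],
                      "mouth_right": [x0 + 0.7 * w, y0 + 0.72 * h]}
                persons.append({
                    "face_box": [x0, y0, x0 + w, y0 + h], "keypoints": kp,
                    "hands": [[x0 - 15, y0 + h, x0 + 15, y0 + h + 30]],
                    "body": [[x0 - 20, y0 + h, x0 + w + 20, y0 + h + 150]]})
            amap = build_frame_aoi_map({"frame": 0, "persons": persons},
                                       screen)
            for _ in range(5):
                x = rng.uniform(0, screen.width_px - 1e-6)
                y = rng.uniform(0, screen.height_px - 1e-6)
                got = coding.assign_frame_aoi(0, x, y, amap, small_config)
                want_coarse, want_fine, want_areas = _oracle_assign(
                    x, y, amap, small_config)
                assert got.coarse == want_coarse
                assert got.fine == want_fine
                for k, v in want_areas.items():
                    assert got.overlap_px[k] == v

    def test_fast_path_matches_single_frame_api(self, small_config):
        rng = np.random.default_rng(8)
        amap = _face_map()
        raster = coding.pad_raster(amap.label_raster(small_config.screen),
                                   small_config)
        xs = rng.uniform(0, small_config.screen.width_px - 1e-6, 200)
        ys = rng.uniform(0, small_config.screen.height_px - 1e-6, 200)
        fast = coding.assign_points_fast(raster, xs, ys, small_config)
        for x, y, code in zip(xs, ys, fast):
            a = coding.assign_frame_aoi(0, x, y, amap, small_config)
            assert COARSE_OF_FINE[code] == a.coarse
            if a.coarse == "face":
                assert {3: "other_face", 4: "eyes", 5: "mouth"}[code] == a.fine


class TestFeatureFractions:
    def test_percentage_arithmetic(self):
        status = np.array([coding.ON_SCREEN] * 80 + [coding.MISSING] * 20,
                          dtype=np.int8)
        fine = np.full(100, -1, np.int8)
        fine[:60] = 3           # face
        fine[60:80] = 0         # non-social
        feats = coding.compute_feature_fractions(fine, status)
        assert feats["pct_onscreen"] == 80.0
        assert feats["pct_face"] == 75.0
        assert feats["pct_nonsocial"] == 25.0

    def test_all_eyes_means_face_and_eyes_100(self):
        status = np.zeros(50, np.int8)
        fine = np.full(50, 4, np.int8)
        feats = coding.compute_feature_fractions(fine, status)
        assert feats["pct_face"] == 100.0 and feats["pct_eyes"] == 100.0

    def test_coarse_percentages_sum_to_100(self, rng):
        status = np.where(rng.random(500) < 0.8, coding.ON_SCREEN,
                          coding.OFF_SCREEN).astype(np.int8)
        fine = rng.integers(0, 6, 500).astype(np.int8)
        fine[status != coding.ON_SCREEN] = -1
        f = coding.compute_feature_fractions(fine, status)
        total = f["pct_face"] + f["pct_nonsocial"] + f["pct_body"] \
            + f["pct_hands"]
        assert abs(total - 100.0) < 1e-9

    def test_zero_onscreen_flags_missing_vector(self):
        status = np.full(10, coding.MISSING, np.int8)
        fine = np.full(10, -1, np.int8)
        feats = coding.compute_feature_fractions(fine, status)
        assert feats["pct_onscreen"] == 0.0
        assert np.isnan(feats["pct_face"])


class TestExclusion:
    def test_exclusion_rules(self):
        summaries = {
            "a": {"EpA": 0.55, "EpB": 0.10},   # > half missing in A
            "b": {"EpA": 0.45, "EpB": 0.45},   # kept
            "c": {"EpA": 0.50, "EpB": 0.50},   # exactly half: kept (strict)
            "d": {"EpA": 0.10},                # incomplete
        }
        kept, excluded = coding.apply_exclusion_criteria(
            summaries, ["EpA", "EpB"], 0.5)
        assert kept == ["b", "c"]
        assert "EpA" in excluded["a"]
        assert excluded["d"] == "incomplete sessions"
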