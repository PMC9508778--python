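import numpy as np
import pytest

from gazepheno import coding, synthetic as syn
from gazepheno.core import GROUP_ASD, GROUP_TD


class TestSceneGeneration:
    def test_same_seed_identical(self, config):
        a = syn.generate_scene("Ep", 30.0, config, seed=5)
        b = syn.generate_scene("Ep", 30.0, config, seed=5)
        assert len(a.shots) == len(b.shots)
        for sa, sb in zip(a.shots, b.shots):
            assert (sa.start_frame, sa.end_frame) == \
                (sb.start_frame, sb.end_frame)
            assert len(sa.persons) == len(sb.persons)
            for pa, pb in zip(sa.persons, sb.persons):
                assert pa.face_box == pb.face_box

    def test_forced_person_prob_every_frame(self, config):
        scene = syn.generate_scene("Ep", 10.0, config, seed=1,
                                   person_prob=1.0)
        assert scene.fraction_frames_with_person() == 1.0

    def test_person_fraction_near_target(self, config):
        scene = syn.generate_scene("Ep", 600.0, config, seed=2,
                                   person_prob=0.96)
        assert abs(scene.fraction_frames_with_person() - 0.96) < 0.02

    def test_subframe_duration_rejected(self, config):
        with pytest.raises(ValueError):
            syn.generate_scene("Ep", 0.01, config, seed=0)

    def test_boxes_inside_screen(self, config):
        scene = syn.generate_scene("Ep", 60.0, config, seed=3)
        W, H = config.screen.width_px, config.screen.height_px
        for shot in scene.shots:
            for p in shot.persons:
                for b in [p.face_box] + p.hands + p.body:
                    assert 0 <= b.x0 < b.x1 <= W
                    assert 0 <= b.y0 < b.y1 <= H


class TestTraitSampling:
    def test_zero_jitter_identical_episode_traits(self):
        spec = syn.CohortSpec(n_asd=3, n_td=3, session_jitter_sd=0.0,
                              rng_seed=0)
        traits = syn.sample_cohort_traits(spec)
        for info in traits.values():
            a, b = info["episodes"].values()
            assert a == b

    def test_zero_between_sd_shares_traits_within_group(self):
        zero_sd = {t: 0.0 for t in syn.PROB_TRAITS}
        spec = syn.CohortSpec(
            n_asd=3, n_td=3, session_jitter_sd=0.0,
            td=syn.GroupTraitSpec(
                components=[(1.0, syn.td_trait_spec().components[0][1])],
                between_sd=zero_sd),
            asd=syn.GroupTraitSpec(
                components=[(1.0, syn.asd_trait_spec().components[0][1])],
                between_sd=zero_sd),
            rng_seed=0)
        traits = syn.sample_cohort_traits(spec)
        td = [info["episodes"]["EpA"] for info in traits.values()
              if info["meta"].group == GROUP_TD]
        assert all(tv == td[0] for tv in td)

    def test_td_face_calibration_monte_carlo(self):
        spec = syn.CohortSpec(n_asd=2, n_td=200, rng_seed=42)
        traits = syn.sample_cohort_traits(spec)
        p_face = [info["episodes"]["EpA"].p_face
                  for info in traits.values()
                  if info["meta"].group == GROUP_TD]
        assert 0.79 <= np.mean(p_face) <= 0.82

    def test_mixture_components_recorded(self):
        spec = syn.hypothesis2_cohort(n_asd=40, n_td=40, seed=3)
        traits = syn.sample_cohort_traits(spec)
        comps = [info["component"] for info in traits.values()
                 if info["meta"].group == GROUP_ASD]
        assert 0.25 < np.mean(comps) < 0.75

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            syn.GroupTraitSpec(components=[(1.0, {})],
                               between_sd={"p_face": -0.1})


class TestGazeSimulation:
    def test_forced_chain_codes_to_eyes(self, config):
        scene = syn.generate_scene("Ep", 20.0, config, seed=4,
                                   person_prob=1.0)
        tv = syn.TraitVector(p_onscreen=1.0, p_face=1.0, p_eyes=1.0,
                             p_mouth=0.0, sigma_spatial_deg=0.0,
                             center_bias=0.0)
        rec = syn.simulate_gaze(tv, scene, config, seed=5)
        fg = coding.downsample_to_frames(rec, 24.0, scene.n_frames, config)
        on = fg.status == coding.ON_SCREEN
        assert on.mean() > 0.95
        labels = np.full(scene.n_frames, -1, np.int8)
        for shot in scene.shots:
            amap = scene.shot_aoi_map(shot, config.screen)
            raster = coding.pad_raster(amap.label_raster(config.screen),
                                       config)
            idx = np.flatnonzero(on[shot.start_frame:shot.end_frame]) \
                + shot.start_frame
            if len(idx):
                labels[idx] = coding.assign_points_fast(
                    raster, fg.x[idx], fg.y[idx], config)
        assert np.all(labels[on] == 4)  # every on-screen frame coded eyes

    def test_zero_onscreen_probability(self, config):
        scene = syn.generate_scene("Ep", 10.0, config, seed=4)
        tv = syn.TraitVector(p_onscreen=0.0, p_face=0.5, p_eyes=0.5,
                             p_mouth=0.2)
        rec = syn.simulate_gaze(tv, scene, config, seed=5)
        assert not rec.onscreen_mask(config.screen).any()

    def test_empty_scene_rejected(self, config):
        scene = syn.SceneSpec("Ep", 10.0, 24.0, shots=[])
        tv = syn.TraitVector(1.0, 0.5, 0.5, 0.2)
        with pytest.raises(ValueError):
            syn.simulate_gaze(tv, scene, config, seed=0)

    def test_trait_invariants_enforced(self):
        with pytest.raises(ValueError):
            syn.TraitVector(p_onscreen=1.1, p_face=0.5, p_eyes=0.3,
                            p_mouth=0.2)
        with pytest.raises(ValueError):
            syn.TraitVector(p_onscreen=0.9, p_face=0.5, p_eyes=0.7,
                            p_mouth=0.5)


class TestCohortGeneration:
    def test_counts_and_determinism(self, config, tmp_path):
        spec = syn.CohortSpec(n_asd=2, n_td=2,
                              episodes=[("EpA", 10.0), ("EpB", 10.0)],
                              rng_seed=9)
        out1 = tmp_path / "run1"
        out2 = tmp_path / "run2"
        recs1, _, _ = syn.make_cohort(spec, config, out_dir=out1)
        recs2, _, _ = syn.make_cohort(spec, config, out_dir=out2)
        assert len(recs1) == 8
        for name in ("gaze_EpA.tsv", "gaze_EpB.tsv", "annotations_EpA.jsonl",
                     "metadata.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_group_face_trait_ordering(self):
        spec = syn.CohortSpec(n_asd=60, n_td=60, rng_seed=5)
        traits = syn.sample_cohort_traits(spec)
        means = {g: np.mean([i["episodes"]["EpA"].p_face
                             for i in traits.values()
                             if i["meta"].group == g])
                 for g in (GROUP_ASD, GROUP_TD)}
        assert means[GROUP_TD] > means[GROUP_ASD]


class TestTraitFeatures:
    def test_noiseless_features_match_trait_arithmetic(self):
        tv = syn.TraitVector(p_onscreen=0.9, p_face=0.8, p_eyes=0.5,
                             p_mouth=0.2)
        f = syn.features_from_traits(tv)
        assert f["pct_onscreen"] == 90.0
        assert f["pct_face"] == 80.0
        assert f["pct_eyes"] == 40.0   # 0.8 * 0.5 of on-screen time
        np.testing.assert_allclose(
            f["pct_face"] + f["pct_nonsocial"] + f["pct_body"]
            + f["pct_hands"], 100.0)
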