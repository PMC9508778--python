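"""Synthetic cohort generator: scenes, traits, and raw gaze streams.

The generator supplies the statistical structure the downstream analyses
assume, so that every stage can be exercised and calibrated without real
recordings:

* **Scenes** are shot-structured: shot durations are lognormal (median ~4 s),
  each shot holds 0-3 persons (a person is present in ~96% of frames by
  default), and each person carries a face box with deterministically placed
  facial keypoints (eyes at 40% of box height, nose at 55%, mouth corners at
  72%), a body box and optional hand boxes.  Persons are static within a
  shot.
* **Traits** are stable per-participant gaze preferences.  Probability
  traits (on-screen, face given on-screen, eyes and mouth given face) live
  on the logit scale: a participant's latent trait is drawn once from their
  group distribution (optionally a mixture of components, which is how a
  heterogeneous group is built), then perturbed independently per episode by
  session jitter.  Group mean shift and between-participant heterogeneity
  are therefore two independent knobs.
* **Gaze** follows a dwell process: a target AOI is drawn from the
  trait-weighted categorical over the AOIs present in the current shot
  (renormalized when a category is absent), the gaze anchor sits at the
  target region's interior anchor point plus Gaussian scatter, is held for
  an exponential dwell (truncated at shot boundaries), and is emitted as raw
  samples at the tracker rate with small per-sample noise.  With probability
  ``1 - p_onscreen`` a dwell is tracker-lost (invalid samples).

Default trait means are calibrated to the observed group face-looking times
of the cohort the pipeline is modelled on (TD ~80.7%, ASD ~77.4% of
on-screen time on faces; eye shares ~60% vs ~52%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aoi import Box, FacialKeypoints, FrameAOIMap, build_frame_aoi_map
from .core import (GROUP_ASD, GROUP_TD, GazeRecording, ParticipantMeta,
                   PipelineConfig, logger)
from . import gaze_io

PROB_TRAITS = ("p_onscreen", "p_face", "p_eyes", "p_mouth")

# How gaze off faces splits between hands, other body and non-social content.
NONFACE_SPLIT = {"hands": 0.12, "other_body": 0.28, "non_social": 0.60}


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class TraitVector:
    """One participant-episode's gaze preference parameters."""

    p_onscreen: float
    p_face: float          # P(face | on-screen)
    p_eyes: float          # P(eyes | face)
    p_mouth: float         # P(mouth | face)
    sigma_spatial_deg: float = 0.4
    center_bias: float = 0.0
    dwell_mean_s: float = 0.5

    def __post_init__(self) -> None:
        for name in PROB_TRAITS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_eyes + self.p_mouth > 1.0 + 1e-9:
            raise ValueError("p_eyes + p_mouth must not exceed 1")
        if self.sigma_spatial_deg < 0:
            raise ValueError("sigma_spatial_deg must be non-negative")


@dataclass
class Person:
    face_box: Box
    keypoints: FacialKeypoints
    hands: list = field(default_factory=list)
    body: list = field(default_factory=list)

    def to_annotation(self) -> dict:
        return {
            "face_box": [self.face_box.x0, self.face_box.y0,
                         self.face_box.x1, self.face_box.y1],
            "keypoints": {k: list(getattr(self.keypoints, k))
                          for k in ("left_eye", "right_eye", "nose",
                                    "mouth_left", "mouth_right")},
            "hands": [[b.x0, b.y0, b.x1, b.y1] for b in self.hands],
            "body": [[b.x0, b.y0, b.x1, b.y1] for b in self.body],
        }


@dataclass
class Shot:
    start_frame: int
    end_frame: int  # half-open
    persons: list


@dataclass
class SceneSpec:
    """A shot-structured synthetic episode."""

    episode_id: str
    duration_s: float
    frame_rate_fps: float
    shots: list

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_fps))

    def shot_of_frame(self, frame: int) -> Shot:
        for shot in self.shots:
            if shot.start_frame <= frame < shot.end_frame:
                return shot
        return self.shots[-1]

    def frame_annotations(self) -> list[dict]:
        out = []
        for shot in self.shots:
            persons = [p.to_annotation() for p in shot.persons]
            for f in range(shot.start_frame, shot.end_frame):
                out.append({"frame": f, "persons": persons})
        return out

    def shot_aoi_map(self, shot: Shot, screen) -> FrameAOIMap:
        ann = {"frame": shot.start_frame,
               "persons": [p.to_annotation() for p in shot.persons]}
        return build_frame_aoi_map(ann, screen)

    def fraction_frames_with_person(self) -> float:
        with_person = sum(s.end_frame - s.start_frame
                          for s in self.shots if s.persons)
        return with_person / self.n_frames


def _make_person(rng: np.random.Generator, screen,
                 other_faces=()) -> Person:
    W, H = screen.width_px, screen.height_px
    h = rng.uniform(120, 210)
    w = 0.8 * h
    # faces of co-present persons must not overlap (occluding faces would
    # make eyes/mouth attribution ambiguous); rejection-sample placement
    for _ in range(30):
        x0 = rng.uniform(0.03 * W, 0.97 * W - w)
        y0 = rng.uniform(0.05 * H, 0.45 * H)
        clear = all(x0 + w + 10 < o.x0 or o.x1 + 10 < x0
                    or y0 + h + 10 < o.y0 or o.y1 + 10 < y0
                    for o in other_faces)
        if clear:
            break
    face = Box(x0, y0, x0 + w, y0 + h)
    kp = FacialKeypoints(
        left_eye=(x0 + 0.30 * w, y0 + 0.40 * h),
        right_eye=(x0 + 0.70 * w, y0 + 0.40 * h),
        nose=(x0 + 0.50 * w, y0 + 0.55 * h),
        mouth_left=(x0 + 0.32 * w, y0 + 0.72 * h),
        mouth_right=(x0 + 0.68 * w, y0 + 0.72 * h),
    )
    bw = 1.8 * w
    bx0 = max(0.0, x0 + 0.5 * w - 0.5 * bw)
    body = Box(bx0, y0 + h, min(W - 1.0, bx0 + bw),
               min(H - 1.0, y0 + h + 2.8 * h))
    hands = []
    for _ in range(rng.integers(0, 3)):
        hx = rng.uniform(max(0.0, bx0 - 30), min(W - 45.0, bx0 + bw))
        hy = rng.uniform(body.y0, max(body.y0 + 1, body.y1 - 45))
        hands.append(Box(hx, hy, hx + 42, hy + 42))
    return Person(face_box=face, keypoints=kp, hands=hands, body=[body])


def generate_scene(episode_id: str, duration_s: float, config: PipelineConfig,
                   seed: int, person_prob: float = 0.96,
                   shot_median_s: float = 4.0,
                   shot_sigma: float = 0.6) -> SceneSpec:
    """Generate a shot-structured scene; deterministic under the seed."""
    fps = config.frame_rate_fps
    n_frames = int(round(duration_s * fps))
    if n_frames < 1:
        raise ValueError("episode shorter than one frame")
    rng = np.random.default_rng(seed)
    shots = []
    f = 0
    while f < n_frames:
        length_s = rng.lognormal(np.log(shot_median_s), shot_sigma)
        length = max(1, int(round(length_s * fps)))
        end = min(n_frames, f + length)
        persons = []
        if rng.random() < person_prob:
            n_persons = 1 + rng.choice(3, p=[0.55, 0.33, 0.12])
            for _ in range(n_persons):
                persons.append(_make_person(
                    rng, config.screen,
                    other_faces=[p.face_box for p in persons]))
        shots.append(Shot(start_frame=f, end_frame=end, persons=persons))
        f = end
    return SceneSpec(episode_id=episode_id, duration_s=duration_s,
                     frame_rate_fps=fps, shots=shots)


@dataclass
class GroupTraitSpec:
    """Trait distribution of one diagnostic group.

    ``components`` is a list of ``(weight, logit-mean dict)`` pairs — or
    ``(weight, means, sd-override dict)`` triples — a single component is the
    homogeneous case, several components build an explicitly heterogeneous
    group.  ``between_sd`` holds logit-scale between-participant SDs (used
    unless a component overrides them); ``fixed`` holds the non-probability
    traits.
    """

    components: list
    between_sd: dict
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.components = [tuple(c) if len(c) == 3 else (c[0], c[1], {})
                           for c in self.components]
        total = sum(c[0] for c in self.components)
        if not np.isclose(total, 1.0):
            raise ValueError("component weights must sum to 1")
        for name, sd in self.between_sd.items():
            if sd < 0:
                raise ValueError(f"between_sd[{name!r}] must be >= 0")


def td_trait_spec() -> GroupTraitSpec:
    return GroupTraitSpec(
        components=[(1.0, {"p_onscreen": logit(0.95), "p_face": logit(0.807),
                           "p_eyes": logit(0.746), "p_mouth": logit(0.18)})],
        between_sd={"p_onscreen": 0.50, "p_face": 0.244,
                    "p_eyes": 0.70, "p_mouth": 0.40},
    )


def asd_trait_spec() -> GroupTraitSpec:
    """Homogeneous ASD spec: group means shifted toward less face/eye gaze."""
    return GroupTraitSpec(
        components=[(1.0, {"p_onscreen": logit(0.93), "p_face": logit(0.774),
                           "p_eyes": logit(0.672), "p_mouth": logit(0.22)})],
        between_sd={"p_onscreen": 0.55, "p_face": 0.33,
                    "p_eyes": 0.70, "p_mouth": 0.40},
    )


# The "atypical gaze" trait profile shared by the heterogeneous-cohort
# components: markedly lower eye-looking and on-screen time, mildly lower
# face-looking, slightly more mouth-looking.
ATYPICAL_MEANS = {"p_onscreen": logit(0.87), "p_face": logit(0.75),
                  "p_eyes": logit(0.42), "p_mouth": logit(0.26)}

# Within-component between-participant SDs for the heterogeneous cohort:
# narrower than the homogeneous specs because part of the observed group
# spread is carried by the component mixture itself.  The atypical component
# is tighter still: it models a coherent gaze style, not a diffuse tail.
_H2_BETWEEN_SD = {"p_onscreen": 0.40, "p_face": 0.24,
                  "p_eyes": 0.55, "p_mouth": 0.35}
_ATYPICAL_SD = {"p_onscreen": 0.25, "p_face": 0.18,
                "p_eyes": 0.35, "p_mouth": 0.30}


def asd_mixture_trait_spec() -> GroupTraitSpec:
    """Heterogeneous ASD spec: 50% near-TD traits, 50% atypical.

    The near-TD component is mildly shifted relative to TD (slightly less
    face/eye looking); the atypical component carries the strong shift.  The
    resulting group means stay close to the homogeneous spec while
    individuals are reliably either near-typical or atypical.
    """
    near_td = {"p_onscreen": logit(0.94), "p_face": logit(0.79),
               "p_eyes": logit(0.72), "p_mouth": logit(0.19)}
    return GroupTraitSpec(
        components=[(0.5, near_td),
                    (0.5, dict(ATYPICAL_MEANS), dict(_ATYPICAL_SD))],
        between_sd=dict(_H2_BETWEEN_SD),
        fixed={"dwell_mean_s": 0.3},
    )


def td_mixture_trait_spec() -> GroupTraitSpec:
    """TD spec with a 25% atypical-gaze minority.

    A quarter of controls share the atypical trait profile, so the atypical
    subgroup crosses diagnostic lines: subgroup structure is discoverable by
    clustering yet barely useful for diagnostic classification.
    """
    typical = td_trait_spec().components[0][1]
    return GroupTraitSpec(
        components=[(0.75, dict(typical)),
                    (0.25, dict(ATYPICAL_MEANS), dict(_ATYPICAL_SD))],
        between_sd=dict(_H2_BETWEEN_SD),
        fixed={"dwell_mean_s": 0.3},
    )


def hypothesis2_cohort(n_asd: int = 30, n_td: int = 60,
                       episode_seconds: float = 300.0,
                       seed: int = 0) -> CohortSpec:
    """The heterogeneous study cohort: reliable individuals, mixed groups.

    Both groups contain the same atypical-gaze trait profile with different
    prevalence (ASD 50%, TD 25%), so the cohort simultaneously shows a
    group-level effect, high within-individual reliability, diagnostic
    classification near chance, and a stable two-cluster subgroup split.
    """
    return CohortSpec(n_asd=n_asd, n_td=n_td,
                      td=td_mixture_trait_spec(),
                      asd=asd_mixture_trait_spec(),
                      session_jitter_sd=0.07,
                      episodes=[("EpA", episode_seconds),
                                ("EpB", episode_seconds)],
                      rng_seed=seed)


@dataclass
class CohortSpec:
    """Synthetic cohort: sizes, group trait distributions, episodes, noise."""

    n_asd: int = 20
    n_td: int = 20
    td: GroupTraitSpec = field(default_factory=td_trait_spec)
    asd: GroupTraitSpec = field(default_factory=asd_trait_spec)
    session_jitter_sd: float = 0.10
    episodes: list = field(default_factory=lambda: [("EpA", 120.0),
                                                    ("EpB", 120.0)])
    person_prob: float = 0.96
    rate_hz: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 2 or self.n_td < 2:
            raise ValueError("need >= 2 participants per group")
        if self.session_jitter_sd < 0:
            raise ValueError("session_jitter_sd must be >= 0")


def paper_scale_cohort(**kw) -> CohortSpec:
    """The full-scale study conditions: 48 ASD / 105 TD, 22+21 min episodes."""
    defaults = dict(n_asd=48, n_td=105,
                    episodes=[("EpA", 22 * 60.0), ("EpB", 21 * 60.0)])
    defaults.update(kw)
    return CohortSpec(**defaults)


def sample_cohort_traits(cohort: CohortSpec, seed: int | None = None) -> dict:
    """Draw per-participant traits (one per episode) and metadata.

    Returns ``{participant_id: {"episodes": {episode_id: TraitVector},
    "meta": ParticipantMeta, "component": int}}``.  The latent trait is drawn
    once per participant on the logit scale, then perturbed per episode by
    session jitter.
    """
    rng = np.random.default_rng(cohort.rng_seed if seed is None else seed)
    out = {}
    groups = ([(GROUP_ASD, i, cohort.asd) for i in range(cohort.n_asd)]
              + [(GROUP_TD, i, cohort.td) for i in range(cohort.n_td)])
    for group, i, spec in groups:
        pid = f"{group.lower()}{i:03d}"
        weights = [c[0] for c in spec.components]
        comp = int(rng.choice(len(weights), p=weights))
        _, means, sd_override = spec.components[comp]
        latent = {t: means[t] + rng.normal(
            0.0, sd_override.get(t, spec.between_sd.get(t, 0.0)))
            for t in PROB_TRAITS}
        fixed = {"sigma_spatial_deg": 0.4, "center_bias": 0.0,
                 "dwell_mean_s": 0.5}
        fixed.update(spec.fixed)
        per_episode = {}
        for ep_id, _dur in cohort.episodes:
            jit = {t: latent[t] + rng.normal(0.0, cohort.session_jitter_sd)
                   for t in PROB_TRAITS}
            probs = {t: float(sigmoid(jit[t])) for t in PROB_TRAITS}
            s = probs["p_eyes"] + probs["p_mouth"]
            if s > 1.0:
                probs["p_eyes"] *= 0.999 / s
                probs["p_mouth"] *= 0.999 / s
            per_episode[ep_id] = TraitVector(**probs, **fixed)
        fam = {ep: int(rng.integers(1, 10)) for ep, _ in cohort.episodes
               if rng.random() > 0.05}
        meta = ParticipantMeta(
            participant_id=pid, group=group,
            site="SiteA" if rng.random() < 0.3 else "SiteB",
            familiarity=fam,
            severity_css=float(np.clip(rng.normal(7.0, 2.0), 3, 10))
            if group == GROUP_ASD else None,
            aq=float(rng.normal(28.1, 7.7) if group == GROUP_ASD
                     else rng.normal(15.7, 6.4)),
            age_years=float(rng.uniform(18, 55)),
            sex="M" if rng.random() < (0.792 if group == GROUP_ASD else 0.705)
            else "F",
        )
        out[pid] = {"episodes": per_episode, "meta": meta, "component": comp}
    return out


def _anchor_points(person: Person, screen) -> dict:
    """Interior anchor points per face sub-region of one person."""
    from .aoi import derive_eyes_mouth_regions, DegenerateSplitError

    fb = person.face_box
    try:
        eyes, mouth = derive_eyes_mouth_regions(fb, person.keypoints)
    except DegenerateSplitError:
        eyes = mouth = None
    center = ((fb.x0 + fb.x1) / 2, (fb.y0 + fb.y1) / 2)
    anchors = {
        "eyes": (((eyes.x0 + eyes.x1) / 2, (eyes.y0 + eyes.y1) / 2)
                 if eyes else center),
        "mouth": (((mouth.x0 + mouth.x1) / 2, (mouth.y0 + mouth.y1) / 2)
                  if mouth else center),
        # chin strip below the medium box: face pixels outside eyes/mouth
        "other_face": ((fb.x0 + fb.x1) / 2,
                       ((mouth.y1 if mouth else fb.y0) + fb.y1) / 2),
    }
    return anchors


def simulate_gaze(traits: TraitVector, scene: SceneSpec,
                  config: PipelineConfig, seed: int,
                  rate_hz: float = 300.0) -> GazeRecording:
    """Simulate one participant-episode raw gaze stream from its traits."""
    if not scene.shots:
        raise ValueError("empty scene")
    if abs(scene.frame_rate_fps - config.frame_rate_fps) > 1e-9:
        raise ValueError("scene and config frame rates differ")
    rng = np.random.default_rng(seed)
    screen = config.screen
    W, H = screen.width_px, screen.height_px
    n = int(round(scene.duration_s * rate_hz))
    t = (np.arange(n) + 0.5) / rate_hz
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    sigma_px = traits.sigma_spatial_deg * screen.px_per_degree
    noise_px = 0.05 * screen.px_per_degree

    tcur = 0.0
    while tcur < scene.duration_s:
        frame = min(int(tcur * scene.frame_rate_fps), scene.n_frames - 1)
        shot = scene.shot_of_frame(frame)
        shot_end_t = shot.end_frame / scene.frame_rate_fps
        dwell = max(rng.exponential(traits.dwell_mean_s), 1.0 / rate_hz)
        t_end = min(tcur + dwell, shot_end_t, scene.duration_s)
        # snap to the next frame boundary: every frame then averages samples
        # from a single dwell, keeping frame-level coding faithful to the
        # dwell targets
        fps = scene.frame_rate_fps
        t_end = min(np.ceil(t_end * fps - 1e-9) / fps, shot_end_t,
                    scene.duration_s)
        i0 = int(np.searchsorted(t, tcur, side="left"))
        i1 = int(np.searchsorted(t, t_end, side="left"))
        if i1 > i0:
            if rng.random() >= traits.p_onscreen:
                pass  # tracker-lost dwell: samples stay invalid
            else:
                anchor = _draw_anchor(traits, shot, screen, rng)
                ax = anchor[0] + rng.normal(0.0, sigma_px)
                ay = anchor[1] + rng.normal(0.0, sigma_px)
                if traits.center_bias > 0:
                    ax = (1 - traits.center_bias) * ax + traits.center_bias * W / 2
                    ay = (1 - traits.center_bias) * ay + traits.center_bias * H / 2
                m = i1 - i0
                x[i0:i1] = ax + rng.normal(0.0, noise_px, m)
                y[i0:i1] = ay + rng.normal(0.0, noise_px, m)
                valid[i0:i1] = True
        tcur = t_end if t_end > tcur else tcur + 1.0 / rate_hz
    return GazeRecording(participant_id="", episode_id=scene.episode_id,
                         rate_hz=rate_hz, t=t, x=x, y=y, valid=valid)


def _draw_anchor(traits: TraitVector, shot: Shot, screen, rng) -> tuple:
    W, H = screen.width_px, screen.height_px
    persons = shot.persons
    has_face = bool(persons)
    has_hands = any(p.hands for p in persons)
    has_body = any(p.body for p in persons)
    # faces keep their trait probability whenever present; mass of absent
    # non-face categories is redistributed within the non-face pool so that
    # P(face | face present) stays exactly p_face
    rest = (1.0 - traits.p_face) if has_face else 1.0
    nonface = {
        "hands": NONFACE_SPLIT["hands"] if has_hands else 0.0,
        "other_body": NONFACE_SPLIT["other_body"] if has_body else 0.0,
        "non_social": NONFACE_SPLIT["non_social"],
    }
    total = sum(nonface.values())
    weights = {c: rest * v / total for c, v in nonface.items()}
    if has_face:
        weights["face"] = traits.p_face
    cats = list(weights)
    w = np.array([weights[c] for c in cats])
    cat = cats[rng.choice(len(cats), p=w / w.sum())]
    if cat == "face":
        person = persons[rng.integers(len(persons))]
        u = rng.random()
        if u < traits.p_eyes:
            sub = "eyes"
        elif u < traits.p_eyes + traits.p_mouth:
            sub = "mouth"
        else:
            sub = "other_face"
        return _anchor_points(person, screen)[sub]
    if cat == "hands":
        boxes = [b for p in persons for b in p.hands]
        b = boxes[rng.integers(len(boxes))]
        return ((b.x0 + b.x1) / 2, (b.y0 + b.y1) / 2)
    if cat == "other_body":
        boxes = [b for p in persons for b in p.body]
        b = boxes[rng.integers(len(boxes))]
        return ((b.x0 + b.x1) / 2, (b.y0 + b.y1) / 2)
    # non-social: a point clear of all person regions (rejection sampling)
    margin = 30.0
    for _ in range(30):
        px = rng.uniform(margin, W - margin)
        py = rng.uniform(margin, H - margin)
        inside = any(b.contains(px, py)
                     for p in persons
                     for b in [p.face_box] + p.hands + p.body)
        if not inside:
            return (px, py)
    return (px, py)


def make_cohort(cohort: CohortSpec, config: PipelineConfig,
                out_dir=None, seed: int | None = None):
    """Generate the full cohort: scenes, traits, recordings, metadata.

    Returns ``(recordings, scenes, traits)`` where ``recordings`` maps
    ``(participant_id, episode_id)`` to a :class:`GazeRecording` and
    ``scenes`` maps episode id to its :class:`SceneSpec`.  When ``out_dir``
    is given, gaze tables (one TSV per episode), annotation JSONL files and
    the metadata CSV are written there.
    """
    base_seed = cohort.rng_seed if seed is None else seed
    root = np.random.default_rng(base_seed)
    scene_seeds = root.integers(0, 2**31 - 1, size=len(cohort.episodes))
    scenes = {ep_id: generate_scene(ep_id, dur, config, int(s),
                                    person_prob=cohort.person_prob)
              for (ep_id, dur), s in zip(cohort.episodes, scene_seeds)}
    traits = sample_cohort_traits(cohort, seed=int(root.integers(2**31 - 1)))

    recordings = {}
    for pid, info in traits.items():
        for ep_id, tv in info["episodes"].items():
            rec = simulate_gaze(tv, scenes[ep_id], config,
                                seed=int(root.integers(2**31 - 1)),
                                rate_hz=cohort.rate_hz)
            rec.participant_id = pid
            recordings[(pid, ep_id)] = rec

    for t in PROB_TRAITS:
        for grp in (GROUP_ASD, GROUP_TD):
            vals = [getattr(tv, t) for pid, info in traits.items()
                    if info["meta"].group == grp
                    for tv in info["episodes"].values()]
            logger.info("realized %s %s: mean %.3f sd %.3f", grp, t,
                        np.mean(vals), np.std(vals))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for ep_id, _ in cohort.episodes:
            gpath = out_dir / f"gaze_{ep_id}.tsv"
            recs = [recordings[(pid, ep_id)] for pid in traits]
            gaze_io.write_gaze_table(recs, gpath)
            apath = out_dir / f"annotations_{ep_id}.jsonl"
            gaze_io.write_annotations(scenes[ep_id].frame_annotations(), apath)
            written += [gpath, apath]
        mpath = out_dir / "metadata.csv"
        gaze_io.write_metadata([info["meta"] for info in traits.values()],
                               mpath)
        written.append(mpath)
        gaze_io.write_manifest(out_dir, "simulate", config, base_seed,
                               outputs=written)
    return recordings, scenes, traits


def scene_from_annotations(frames: list, episode_id: str,
                           frame_rate_fps: float = 24.0) -> SceneSpec:
    """Rebuild a shot-structured scene from per-frame annotation objects.

    Consecutive frames with identical person annotations are grouped into
    one shot, so detections that are static across a camera shot (as this
    generator emits) round-trip exactly.
    """
    if not frames:
        raise ValueError("no annotation frames")
    frames = sorted(frames, key=lambda f: f["frame"])

    def _person(d: dict) -> Person:
        return Person(
            face_box=Box(*d["face_box"]),
            keypoints=FacialKeypoints(**{k: tuple(v)
                                         for k, v in d["keypoints"].items()}),
            hands=[Box(*b) for b in d.get("hands", [])],
            body=[Box(*b) for b in d.get("body", [])])

    shots = []
    start = frames[0]["frame"]
    prev = frames[0]["persons"]
    for f in frames[1:]:
        if f["persons"] != prev:
            shots.append(Shot(start, f["frame"],
                              [_person(p) for p in prev]))
            start = f["frame"]
            prev = f["persons"]
    last = frames[-1]["frame"] + 1
    shots.append(Shot(start, last, [_person(p) for p in prev]))
    return SceneSpec(episode_id=episode_id, duration_s=last / frame_rate_fps,
                     frame_rate_fps=frame_rate_fps, shots=shots)


# ---------------------------------------------------------------------------
# Trait-level (noiseless) features: the deterministic expectation of the
# pipeline's 8 features given a trait vector.  Used to study the resampling
# statistics in isolation from gaze-simulation noise.
# ---------------------------------------------------------------------------

def features_from_traits(tv: TraitVector) -> dict:
    rest = 1.0 - tv.p_face
    return {
        "pct_onscreen": 100.0 * tv.p_onscreen,
        "pct_face": 100.0 * tv.p_face,
        "pct_nonsocial": 100.0 * rest * NONFACE_SPLIT["non_social"],
        "pct_body": 100.0 * rest * NONFACE_SPLIT["other_body"],
        "pct_hands": 100.0 * rest * NONFACE_SPLIT["hands"],
        "pct_eyes": 100.0 * tv.p_face * tv.p_eyes,
        "pct_mouth": 100.0 * tv.p_face * tv.p_mouth,
        "mean_heatmap_corr": 0.35 + 0.35 * tv.p_face + 0.10 * tv.p_onscreen,
    }


def trait_feature_table(traits: dict):
    """(participants x episodes) noiseless feature table as a DataFrame."""
    import pandas as pd

    rows = []
    for pid, info in traits.items():
        for ep_id, tv in info["episodes"].items():
            row = {"participant_id": pid, "episode_id": ep_id,
                   "group": info["meta"].group}
            row.update(features_from_traits(tv))
            rows.append(row)
    return pd.DataFrame(rows)
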