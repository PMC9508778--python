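"""Shared plumbing for the numbered analysis scripts.

The study cohort lives under ``results/cohort/`` (gaze tables, annotation
JSONL, metadata CSV); every analysis script loads it from disk and rebuilds
the coded timeline, so each step is reproducible from the files alone.
"""

from pathlib import Path

from gazepheno import gaze_io, synthetic as syn
from gazepheno.core import PipelineConfig
from gazepheno.timeline import build_timeline

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "results" / "cohort"
RESULTS_DIR = ROOT / "results"

SEED = 20260923
EPISODE_SECONDS = 300.0


def default_config() -> PipelineConfig:
    return PipelineConfig(heatmap_downsample=4, rng_seed=SEED)


def cohort_spec() -> syn.CohortSpec:
    """The study cohort: heterogeneous groups, two 5-minute episodes."""
    return syn.hypothesis2_cohort(n_asd=30, n_td=60,
                                  episode_seconds=EPISODE_SECONDS, seed=SEED)


def load_cohort(config: PipelineConfig):
    """Load recordings, scenes and metadata from results/cohort/."""
    episode_ids = sorted(p.stem.replace("gaze_", "")
                         for p in COHORT_DIR.glob("gaze_*.tsv"))
    if not episode_ids:
        raise SystemExit("no cohort on disk; run 01_simulate_cohort.py first")
    recordings = {}
    scenes = {}
    for ep in episode_ids:
        for rec in gaze_io.read_gaze_table(COHORT_DIR / f"gaze_{ep}.tsv"):
            recordings[(rec.participant_id, rec.episode_id)] = rec
        frames = gaze_io.read_annotations(COHORT_DIR
                                          / f"annotations_{ep}.jsonl")
        scenes[ep] = syn.scene_from_annotations(frames, ep,
                                                config.frame_rate_fps)
    metas = {m.participant_id: m
             for m in gaze_io.read_metadata(COHORT_DIR / "metadata.csv")}
    return recordings, scenes, metas


def load_timeline(config: PipelineConfig):
    recordings, scenes, metas = load_cohort(config)
    return build_timeline(recordings, scenes, metas, config)
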