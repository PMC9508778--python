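"""The coded cohort timeline: per-frame AOI labels and per-bin heatmap
correlations for every kept participant, concatenated across episodes.

Building the timeline runs the whole coding front-end once (downsampling,
exclusion, disk-overlap AOI assignment against per-shot label rasters,
per-bin leave-one-out reference-heatmap correlation).  The resulting
cumulative-count arrays make the gaze feature vector of any contiguous epoch
an O(participants) lookup, which is what the 10,000-iteration resampling
analyses (effect sizes, reliability, fingerprinting, classification,
clustering) slice into.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coding, heatmaps
from .core import FEATURES_8, GROUP_TD, PipelineConfig, logger


@dataclass
class CohortTimeline:
    """Coded gaze of a cohort on the combined two-episode timeline."""

    pids: list
    groups: np.ndarray            # group label per participant
    config: PipelineConfig
    episode_ids: list
    episode_frame_ranges: dict    # episode_id -> (f0, f1) on the timeline
    n_frames: int
    n_bins: int
    total_seconds: float
    # cumulative counts over frames, shape (P, n_frames + 1)
    cum_onscreen: np.ndarray
    cum_labels: np.ndarray        # (P, 6, n_frames + 1) fine-label counts
    # cumulative heatmap-correlation sums over bins, shape (P, n_bins + 1)
    cum_r: np.ndarray
    cum_r_count: np.ndarray
    metas: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.pids)

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)

    def _frame_range(self, start_s: float, duration_s: float):
        fps = self.config.frame_rate_fps
        f0 = int(round(start_s * fps))
        f1 = f0 + int(round(duration_s * fps))
        return max(f0, 0), min(f1, self.n_frames)

    def _bin_range(self, start_s: float, duration_s: float):
        bs = self.config.bin_seconds
        b0 = int(round(start_s / bs))
        b1 = b0 + int(round(duration_s / bs))
        return max(b0, 0), min(b1, self.n_bins)

    def feature_matrix(self, start_s: float = 0.0,
                       duration_s: float | None = None) -> np.ndarray:
        """(P, 8) feature matrix for a contiguous epoch of the timeline.

        Columns follow :data:`gazepheno.core.FEATURES_8`.  AOI percentages
        are NaN for participants with no on-screen frame in the epoch; the
        heatmap correlation is NaN when no bin is defined.
        """
        if duration_s is None:
            duration_s = self.total_seconds - start_s
        f0, f1 = self._frame_range(start_s, duration_s)
        b0, b1 = self._bin_range(start_s, duration_s)
        if f1 <= f0:
            raise ValueError("epoch contains no frames")
        total = f1 - f0
        on = (self.cum_onscreen[:, f1] - self.cum_onscreen[:, f0]).astype(float)
        counts = (self.cum_labels[:, :, f1] - self.cum_labels[:, :, f0]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.where(on > 0, on, np.nan)
            face = counts[:, 3] + counts[:, 4] + counts[:, 5]
            rsum = self.cum_r[:, b1] - self.cum_r[:, b0]
            rcount = self.cum_r_count[:, b1] - self.cum_r_count[:, b0]
            mean_r = np.where(rcount > 0, rsum / np.maximum(rcount, 1), np.nan)
            out = np.column_stack([
                100.0 * on / total,
                100.0 * face / denom,
                100.0 * counts[:, 0] / denom,
                100.0 * counts[:, 1] / denom,
                100.0 * counts[:, 2] / denom,
                100.0 * counts[:, 4] / denom,
                100.0 * counts[:, 5] / denom,
                mean_r,
            ])
        return out

    def feature_frame(self, start_s: float = 0.0,
                      duration_s: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.feature_matrix(start_s, duration_s),
                          columns=list(FEATURES_8))
        df.insert(0, "participant_id", self.pids)
        df.insert(1, "group", self.groups)
        return df

    def episode_features(self, episode_id: str) -> pd.DataFrame:
        f0, f1 = self.episode_frame_ranges[episode_id]
        fps = self.config.frame_rate_fps
        return self.feature_frame(f0 / fps, (f1 - f0) / fps)


def build_timeline(recordings: dict, scenes: dict, metas: dict,
                   config: PipelineConfig,
                   reference_group: str = GROUP_TD,
                   apply_exclusion: bool = True,
                   flag_outliers: bool = True) -> CohortTimeline:
    """Run the coding front-end and assemble the cohort timeline.

    ``recordings`` maps ``(participant_id, episode_id)`` to raw recordings,
    ``scenes`` maps episode id to a scene (shot-structured annotation), and
    ``metas`` maps participant id to :class:`ParticipantMeta`.  Participants
    missing more than half of either episode are excluded, as are
    (optionally) mean-heatmap-correlation outliers beyond 4 SD.
    """
    episode_ids = list(scenes)
    pids = sorted({pid for pid, _ in recordings})

    # 1. downsample to frame rate
    fg: dict[tuple, coding.FrameGazeSeries] = {}
    for (pid, ep), rec in recordings.items():
        fg[(pid, ep)] = coding.downsample_to_frames(
            rec, config.frame_rate_fps, scenes[ep].n_frames, config)

    # 2. exclusion on missing-data fraction
    summaries = {pid: {ep: fg[(pid, ep)].not_onscreen_fraction
                       for ep in episode_ids if (pid, ep) in fg}
                 for pid in pids}
    if apply_exclusion:
        kept, excluded = coding.apply_exclusion_criteria(
            summaries, episode_ids, config.exclusion_missing_fraction)
    else:
        kept, excluded = list(pids), {}

    # 3. AOI-code every on-screen frame, episode by episode, shot by shot
    fine: dict[str, np.ndarray] = {}
    for pid in kept:
        fine[pid] = np.full(sum(scenes[ep].n_frames for ep in episode_ids),
                            -1, dtype=np.int8)
    offsets = {}
    off = 0
    for ep in episode_ids:
        offsets[ep] = off
        scene = scenes[ep]
        for shot in scene.shots:
            amap = scene.shot_aoi_map(shot, config.screen)
            raster = coding.pad_raster(amap.label_raster(config.screen),
                                       config)
            for pid in kept:
                series = fg[(pid, ep)]
                sl = slice(shot.start_frame, shot.end_frame)
                on = series.status[sl] == coding.ON_SCREEN
                if not on.any():
                    continue
                idx = np.flatnonzero(on) + shot.start_frame
                labels = coding.assign_points_fast(
                    raster, series.x[idx], series.y[idx], config)
                fine[pid][idx + off] = labels
        off += scene.n_frames
    n_frames = off

    # 4. per-bin reference-heatmap correlations (concatenated over episodes)
    bin_s = config.bin_seconds
    fps = config.frame_rate_fps
    r_rows = []
    n_bins_total = 0
    per_episode_r = []
    ref_ids = [pid for pid in kept if metas[pid].group == reference_group]
    for ep in episode_ids:
        scene = scenes[ep]
        n_bins = int(round(scene.duration_s / bin_s))
        n_bins_total += n_bins
        frames_per_bin = int(round(bin_s * fps))
        bin_points = {}
        for pid in kept:
            series = fg[(pid, ep)]
            pts = []
            for b in range(n_bins):
                sl = slice(b * frames_per_bin,
                           min((b + 1) * frames_per_bin, scene.n_frames))
                on = series.status[sl] == coding.ON_SCREEN
                idx = np.flatnonzero(on) + sl.start
                pts.append((series.x[idx], series.y[idx]))
            bin_points[pid] = pts
        series_by_pid = heatmaps.reference_correlation_bins(
            bin_points, ref_ids, config, reference_group)
        per_episode_r.append({pid: series_by_pid[pid].r for pid in kept})

    r_all = {pid: np.concatenate([er[pid] for er in per_episode_r])
             for pid in kept}

    # 5. 4-SD outlier exclusion on mean reference correlation
    if flag_outliers and len(kept) >= 3:
        mean_r = {}
        for pid in kept:
            defined = r_all[pid][np.isfinite(r_all[pid])]
            mean_r[pid] = defined.mean() if len(defined) else np.nan
        flags = heatmaps.flag_heatmap_outliers(mean_r)
        for pid, bad in flags.items():
            if bad:
                excluded[pid] = "heatmap correlation outlier (> 4 SD)"
                kept.remove(pid)
                logger.info("excluded %s: heatmap outlier", pid)

    # 6. cumulative arrays
    P = len(kept)
    cum_on = np.zeros((P, n_frames + 1), dtype=np.int32)
    cum_lab = np.zeros((P, 6, n_frames + 1), dtype=np.int32)
    cum_r = np.zeros((P, n_bins_total + 1))
    cum_rc = np.zeros((P, n_bins_total + 1), dtype=np.int32)
    for i, pid in enumerate(kept):
        lab = fine[pid]
        cum_on[i, 1:] = np.cumsum(lab >= 0)
        for code in range(6):
            cum_lab[i, code, 1:] = np.cumsum(lab == code)
        r = r_all[pid]
        ok = np.isfinite(r)
        cum_r[i, 1:] = np.cumsum(np.where(ok, r, 0.0))
        cum_rc[i, 1:] = np.cumsum(ok)

    ranges = {}
    for ep in episode_ids:
        ranges[ep] = (offsets[ep], offsets[ep] + scenes[ep].n_frames)
    return CohortTimeline(
        pids=list(kept),
        groups=np.array([metas[pid].group for pid in kept]),
        config=config,
        episode_ids=episode_ids,
        episode_frame_ranges=ranges,
        n_frames=n_frames,
        n_bins=n_bins_total,
        total_seconds=n_frames / fps,
        cum_onscreen=cum_on,
        cum_labels=cum_lab,
        cum_r=cum_r,
        cum_r_count=cum_rc,
        metas={pid: metas[pid] for pid in kept},
        excluded=excluded,
    )


def timeline_from_traits(traits: dict, episode_seconds: float = 600.0,
                         config: PipelineConfig | None = None
                         ) -> "TraitTimeline":
    """A lightweight timeline whose epoch features are trait expectations.

    Every epoch inside an episode returns that episode's noiseless feature
    vector (the deterministic expectation of the pipeline features given the
    traits), so resampling statistics can be studied without simulation
    noise.  Epochs are attributed to the episode containing their start.
    """
    from .synthetic import features_from_traits

    pids = sorted(traits)
    episode_ids = list(next(iter(traits.values()))["episodes"])
    feats = {ep: np.array([list(features_from_traits(
        traits[pid]["episodes"][ep]).values()) for pid in pids])
        for ep in episode_ids}
    groups = np.array([traits[pid]["meta"].group for pid in pids])
    return TraitTimeline(pids=pids, groups=groups, episode_ids=episode_ids,
                         episode_seconds=episode_seconds, features=feats,
                         metas={p: traits[p]["meta"] for p in pids})


@dataclass
class TraitTimeline:
    """Noiseless stand-in for :class:`CohortTimeline` (trait expectations)."""

    pids: list
    groups: np.ndarray
    episode_ids: list
    episode_seconds: float
    features: dict
    metas: dict

    @property
    def n_participants(self) -> int:
        return len(self.pids)

    @property
    def total_seconds(self) -> float:
        return self.episode_seconds * len(self.episode_ids)

    def group_indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)

    def feature_matrix(self, start_s: float = 0.0,
                       duration_s: float | None = None) -> np.ndarray:
        ep_idx = min(int(start_s // self.episode_seconds),
                     len(self.episode_ids) - 1)
        return self.features[self.episode_ids[ep_idx]].copy()

    def feature_frame(self, start_s: float = 0.0,
                      duration_s: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.feature_matrix(start_s, duration_s),
                          columns=list(FEATURES_8))
        df.insert(0, "participant_id", self.pids)
        df.insert(1, "group", self.groups)
        return df
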