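"""Gaze-to-AOI coding: frame-rate downsampling, disk-overlap assignment,
feature fractions and participant exclusion.

Raw gaze (120 or 300 Hz) is reduced to one mean gaze point per video frame;
each on-screen frame's point is represented as a disk of 1 degree visual
angle and assigned to the AOI with the maximum rasterized overlap (coarse
level first, then eyes/mouth/other-face within the face).  A pixel belongs to
the disk iff its centre lies within the radius (20.5 px at defaults).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aoi import COARSE_OF_FINE, FrameAOIMap
from .core import GazeRecording, PipelineConfig, logger

ON_SCREEN, OFF_SCREEN, MISSING = 0, 1, 2

COARSE_ORDER = ("face", "hands", "other_body", "non_social")  # tie-break order
FINE_ORDER = ("eyes", "mouth", "other_face")


@dataclass
class FrameGazeSeries:
    """Per-frame mean gaze of one recording (arrays over frame index)."""

    x: np.ndarray        # mean gaze x, NaN where no valid samples
    y: np.ndarray
    n_valid: np.ndarray  # valid samples per frame
    status: np.ndarray   # ON_SCREEN / OFF_SCREEN / MISSING

    def __len__(self) -> int:
        return len(self.x)

    @property
    def not_onscreen_fraction(self) -> float:
        return float(np.mean(self.status != ON_SCREEN))


def downsample_to_frames(rec: GazeRecording, frame_rate: float, n_frames: int,
                         config: PipelineConfig) -> FrameGazeSeries:
    """Average valid samples within each frame span [f/fps, (f+1)/fps).

    A sample exactly on a frame boundary belongs to the later frame.  Frames
    with zero valid samples are ``MISSING``; frames whose mean point falls
    outside the screen are ``OFF_SCREEN``.  The reduction is rate-agnostic,
    so 300 Hz and 120 Hz recordings are treated identically.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if rec.rate_hz <= frame_rate:
        raise ValueError("recording rate must exceed the frame rate")
    frame_idx = np.floor(rec.t * frame_rate).astype(np.int64)
    keep = (frame_idx >= 0) & (frame_idx < n_frames)
    frame_idx = frame_idx[keep]
    valid = rec.valid[keep]

    n_valid = np.bincount(frame_idx[valid], minlength=n_frames)
    sx = np.bincount(frame_idx[valid], weights=rec.x[keep][valid],
                     minlength=n_frames)
    sy = np.bincount(frame_idx[valid], weights=rec.y[keep][valid],
                     minlength=n_frames)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(n_valid > 0, sx / np.maximum(n_valid, 1), np.nan)
        my = np.where(n_valid > 0, sy / np.maximum(n_valid, 1), np.nan)

    status = np.full(n_frames, MISSING, dtype=np.int8)
    has = n_valid > 0
    inside = np.zeros(n_frames, dtype=bool)
    inside[has] = config.screen.contains(mx[has], my[has])
    status[has & inside] = ON_SCREEN
    status[has & ~inside] = OFF_SCREEN
    return FrameGazeSeries(x=mx, y=my, n_valid=n_valid, status=status)


def _disk_counts(labels: np.ndarray, px0: int, py0: int,
                 x: float, y: float, radius: float) -> np.ndarray:
    """Per-fine-label pixel counts of the disk over a label patch.

    ``labels`` covers pixels [px0, px0+w) x [py0, py0+h); entries < 0 mark
    off-screen padding and are excluded from every AOI count.
    """
    h, w = labels.shape
    ix = px0 + np.arange(w)
    iy = py0 + np.arange(h)
    mask = ((ix[None, :] - x) ** 2 + (iy[:, None] - y) ** 2) <= radius ** 2
    sel = labels[mask]
    sel = sel[sel >= 0]
    return np.bincount(sel, minlength=6)


def _argmax_with_order(values: dict[str, float], order: tuple) -> str:
    best = max(values.values())
    for name in order:
        if values[name] == best:
            return name
    raise AssertionError("unreachable")


@dataclass
class AOIAssignment:
    frame: int
    coarse: str   # face / hands / other_body / non_social / none
    fine: str     # eyes / mouth / other_face / n/a
    overlap_px: dict


def assign_frame_aoi(frame: int, x: float, y: float, aoi: FrameAOIMap,
                     config: PipelineConfig) -> AOIAssignment:
    """Assign one on-screen frame's mean gaze point to an AOI.

    The coarse label is the argmax of disk overlap among face / hands /
    other-body / non-social (ties broken in that order); when the face wins,
    the fine label is the overlap argmax among eyes / mouth / other-face
    (ties broken in that order).
    """
    if not np.isfinite(x) or not np.isfinite(y):
        raise ValueError("assign_frame_aoi requires an on-screen frame")
    screen = config.screen
    if not screen.contains(np.array(x), np.array(y)):
        raise ValueError("assign_frame_aoi requires an on-screen gaze point")
    r = config.disk_radius_px
    px0 = max(int(np.ceil(x - r)), 0)
    px1 = min(int(np.floor(x + r)) + 1, screen.width_px)
    py0 = max(int(np.ceil(y - r)), 0)
    py1 = min(int(np.floor(y + r)) + 1, screen.height_px)
    patch = aoi.label_patch(px0, py0, px1, py1)
    counts = _disk_counts(patch, px0, py0, x, y, r)

    coarse_counts = {
        "non_social": int(counts[0]),
        "other_body": int(counts[1]),
        "hands": int(counts[2]),
        "face": int(counts[3] + counts[4] + counts[5]),
    }
    coarse = _argmax_with_order(coarse_counts, COARSE_ORDER)
    fine = "n/a"
    if coarse == "face":
        fine_counts = {"other_face": int(counts[3]), "eyes": int(counts[4]),
                       "mouth": int(counts[5])}
        fine = _argmax_with_order(fine_counts, FINE_ORDER)
    overlap = dict(coarse_counts)
    if coarse == "face":
        overlap.update({"eyes": int(counts[4]), "mouth": int(counts[5]),
                        "other_face": int(counts[3])})
    return AOIAssignment(frame=frame, coarse=coarse, fine=fine,
                         overlap_px=overlap)


# Integer coding of assignments on the timeline: -1 = frame not on-screen,
# otherwise index into ASSIGN_LABELS of the (coarse, fine) pair.
ASSIGN_LABELS = ("non_social", "other_body", "hands",
                 "face/other_face", "face/eyes", "face/mouth")


def assign_points_fast(raster: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                       config: PipelineConfig) -> np.ndarray:
    """Vectorized-per-point AOI assignment against a padded label raster.

    ``raster`` must be the frame's fine-label raster padded on every side by
    ``pad = ceil(radius) + 1`` pixels of the sentinel value -1.  Produces the
    same labels as :func:`assign_frame_aoi`, exactly.
    """
    r = config.disk_radius_px
    pad = int(np.ceil(r)) + 1
    span = np.arange(-pad, pad + 1)
    out = np.empty(len(xs), dtype=np.int8)
    dx2 = np.empty((len(span), len(span)))
    for i, (x, y) in enumerate(zip(xs, ys)):
        ix0, iy0 = int(np.floor(x)), int(np.floor(y))
        fx, fy = x - ix0, y - iy0
        np.add((span[None, :] - fx) ** 2, (span[:, None] - fy) ** 2, out=dx2)
        window = raster[iy0:iy0 + 2 * pad + 1, ix0:ix0 + 2 * pad + 1]
        sel = window[dx2 <= r * r]
        counts = np.bincount(sel[sel >= 0], minlength=6)
        face = counts[3] + counts[4] + counts[5]
        top = max(face, counts[2], counts[1], counts[0])
        if face == top:
            if counts[4] >= counts[5] and counts[4] >= counts[3]:
                out[i] = 4
            elif counts[5] >= counts[3]:
                out[i] = 5
            else:
                out[i] = 3
        elif counts[2] == top:
            out[i] = 2
        elif counts[1] == top:
            out[i] = 1
        else:
            out[i] = 0
    return out


def pad_raster(raster: np.ndarray, config: PipelineConfig) -> np.ndarray:
    pad = int(np.ceil(config.disk_radius_px)) + 1
    return np.pad(raster, pad, constant_values=-1)


def compute_feature_fractions(fine_labels: np.ndarray,
                              status: np.ndarray) -> dict:
    """AOI percentages from per-frame fine labels and statuses.

    ``pct_onscreen`` is over all frames; every other percentage is over
    on-screen frames ("frames with successful on-screen gaze").  Eyes and
    mouth are fine-level shares, hence each bounded by ``pct_face``.  With
    zero on-screen frames the AOI percentages are undefined and the vector is
    flagged missing (NaN).
    """
    total = len(status)
    if total == 0:
        raise ValueError("empty frame sequence")
    on = status == ON_SCREEN
    n_on = int(on.sum())
    feats = {"pct_onscreen": 100.0 * n_on / total}
    if n_on == 0:
        for k in ("pct_face", "pct_nonsocial", "pct_body", "pct_hands",
                  "pct_eyes", "pct_mouth"):
            feats[k] = np.nan
        return feats
    lab = fine_labels[on]
    counts = np.bincount(lab, minlength=6)
    feats["pct_nonsocial"] = 100.0 * counts[0] / n_on
    feats["pct_body"] = 100.0 * counts[1] / n_on
    feats["pct_hands"] = 100.0 * counts[2] / n_on
    feats["pct_face"] = 100.0 * (counts[3] + counts[4] + counts[5]) / n_on
    feats["pct_eyes"] = 100.0 * counts[4] / n_on
    feats["pct_mouth"] = 100.0 * counts[5] / n_on
    return feats


def apply_exclusion_criteria(summaries: dict, episode_ids: list,
                             threshold: float = 0.5):
    """Exclude participants missing more than half of either episode.

    ``summaries`` maps ``participant_id -> {episode_id: fraction of frames
    not on-screen}``.  Exclusion is strict (> threshold); a participant with
    exactly the threshold fraction is kept.  Participants lacking an episode
    are excluded with reason ``incomplete sessions``.
    """
    kept, excluded = [], {}
    for pid, per_ep in summaries.items():
        if set(episode_ids) - set(per_ep):
            excluded[pid] = "incomplete sessions"
            continue
        bad = [ep for ep in episode_ids if per_ep[ep] > threshold]
        if bad:
            excluded[pid] = (f"missing fraction > {threshold:g} in "
                             + ", ".join(bad))
        else:
            kept.append(pid)
    for pid, reason in excluded.items():
        logger.info("excluded %s: %s", pid, reason)
    return kept, excluded
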