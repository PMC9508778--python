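"""Gaussian gaze heatmaps, leave-one-out reference maps and correlations.

For each 1-s time bin a participant's heatmap is the sum of isotropic
Gaussian kernels (sigma = 0.5 degree of visual angle by default, truncated at
4 sigma) centred at each of the participant's gaze points in the bin.  A
group's reference heatmap for a bin pools the gaze points of all group
members; when the compared participant belongs to the reference group the
reference always leaves that participant out.  Heatmaps are compared by
Pearson correlation of the flattened grids.

Grids may be computed on an integer-downsampled pixel grid
(``config.heatmap_downsample``); correlations are stable to this factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import PipelineConfig, logger

_TRUNC_SIGMAS = 4.0


@lru_cache(maxsize=8)
def _kernel(sigma: float) -> np.ndarray:
    """Truncated 2-D Gaussian kernel on the (possibly downsampled) grid."""
    half = int(np.ceil(_TRUNC_SIGMAS * sigma))
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (ax / sigma) ** 2)
    k = np.outer(g, g)
    k[np.add.outer(ax**2, ax**2) > (_TRUNC_SIGMAS * sigma) ** 2] = 0.0
    return k


@dataclass
class Heatmap:
    """One time bin's gaze density grid."""

    grid: np.ndarray
    bin_index: int
    bin_seconds: float
    sigma_px: float
    downsample: int
    n_points: int

    @property
    def empty(self) -> bool:
        return self.n_points == 0


def _grid_shape(config: PipelineConfig) -> tuple[int, int]:
    ds = config.heatmap_downsample
    return (-(-config.screen.height_px // ds), -(-config.screen.width_px // ds))


def _stamp(grid: np.ndarray, xs: np.ndarray, ys: np.ndarray,
           config: PipelineConfig) -> None:
    ds = config.heatmap_downsample
    kern = _kernel(config.sigma_px / ds)
    half = kern.shape[0] // 2
    h, w = grid.shape
    for x, y in zip(xs, ys):
        cx = int(round(x / ds))
        cy = int(round(y / ds))
        x0, x1 = cx - half, cx + half + 1
        y0, y1 = cy - half, cy + half + 1
        kx0, ky0 = max(0, -x0), max(0, -y0)
        kx1 = kern.shape[1] - max(0, x1 - w)
        ky1 = kern.shape[0] - max(0, y1 - h)
        if kx0 >= kx1 or ky0 >= ky1:
            continue
        grid[max(0, y0):min(h, y1), max(0, x0):min(w, x1)] += \
            kern[ky0:ky1, kx0:kx1]


def rasterize_heatmap(xs, ys, config: PipelineConfig,
                      bin_index: int = 0) -> Heatmap:
    """Heatmap of the given on-screen gaze points (empty bin -> zero grid)."""
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    ys = np.atleast_1d(np.asarray(ys, dtype=float))
    grid = np.zeros(_grid_shape(config))
    _stamp(grid, xs, ys, config)
    return Heatmap(grid=grid, bin_index=bin_index,
                   bin_seconds=config.bin_seconds, sigma_px=config.sigma_px,
                   downsample=config.heatmap_downsample, n_points=len(xs))


def reference_heatmap(points_by_participant: dict, config: PipelineConfig,
                      leave_out: str | None = None,
                      bin_index: int = 0) -> Heatmap:
    """Pooled group heatmap for one bin, optionally leaving one member out.

    ``points_by_participant`` maps participant id to ``(xs, ys)`` for the
    bin.  A ``leave_out`` id not present in the group yields the full-group
    reference; an empty group after leave-out is an error.
    """
    members = [pid for pid in points_by_participant if pid != leave_out]
    if not members:
        raise ValueError("reference group empty after leave-one-out")
    xs = np.concatenate([np.atleast_1d(points_by_participant[m][0])
                         for m in members]) if members else np.array([])
    ys = np.concatenate([np.atleast_1d(points_by_participant[m][1])
                         for m in members])
    return rasterize_heatmap(xs, ys, config, bin_index=bin_index)


def correlate_heatmaps(h1, h2) -> float:
    """Pearson correlation of two flattened grids; NaN when undefined."""
    g1 = h1.grid if isinstance(h1, Heatmap) else np.asarray(h1)
    g2 = h2.grid if isinstance(h2, Heatmap) else np.asarray(h2)
    if g1.shape != g2.shape:
        raise ValueError("heatmap grids differ in shape")
    v1 = g1.ravel()
    v2 = g2.ravel()
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        return np.nan
    v1 = v1 - v1.mean()
    v2 = v2 - v2.mean()
    return float(v1 @ v2 / np.sqrt((v1 @ v1) * (v2 @ v2)))


@dataclass
class ReferenceCorrSeries:
    participant_id: str
    r: np.ndarray          # per-bin Pearson r, NaN where undefined
    reference_group: str

    @property
    def mean_r(self) -> float:
        defined = self.r[np.isfinite(self.r)]
        return float(defined.mean()) if len(defined) else np.nan


def reference_correlation_bins(bin_points: dict, ref_ids: list,
                               config: PipelineConfig,
                               reference_group: str = "TD"
                               ) -> dict[str, ReferenceCorrSeries]:
    """Per-bin reference correlations for every participant at once.

    ``bin_points`` maps participant id to a list over bins of ``(xs, ys)``
    on-screen point arrays.  For each bin, each participant's heatmap is
    correlated with the pooled reference-group heatmap, leaving the
    participant out iff they belong to the reference group.  Bins where the
    participant has no points, or where either grid is constant, stay NaN.
    """
    pids = list(bin_points)
    n_bins = len(next(iter(bin_points.values())))
    ref_set = set(ref_ids)
    out = {pid: np.full(n_bins, np.nan) for pid in pids}
    shape = _grid_shape(config)
    for b in range(n_bins):
        maps = {}
        for pid in pids:
            xs, ys = bin_points[pid][b]
            if len(np.atleast_1d(xs)) == 0:
                maps[pid] = None
                continue
            g = np.zeros(shape)
            _stamp(g, np.atleast_1d(xs), np.atleast_1d(ys), config)
            maps[pid] = g
        ref_members = [p for p in ref_ids if maps.get(p) is not None]
        if not ref_members:
            continue
        ref_total = np.zeros(shape)
        for p in ref_members:
            ref_total += maps[p]
        for pid in pids:
            own = maps[pid]
            if own is None:
                continue
            ref = ref_total - own if pid in ref_set else ref_total
            out[pid][b] = correlate_heatmaps(own, ref)
    return {pid: ReferenceCorrSeries(pid, out[pid], reference_group)
            for pid in pids}


def participant_reference_correlation(pid: str, bin_points: dict,
                                      ref_ids: list, config: PipelineConfig,
                                      reference_group: str = "TD"
                                      ) -> ReferenceCorrSeries:
    """Reference-correlation series for a single participant."""
    series = reference_correlation_bins(bin_points, ref_ids, config,
                                        reference_group)[pid]
    if not np.any(np.isfinite(series.r)):
        logger.warning("participant %s has no defined heatmap bins", pid)
    return series


def flag_heatmap_outliers(mean_r: dict[str, float],
                          n_sd: float = 4.0) -> dict[str, bool]:
    """Flag participants whose mean reference correlation is extreme.

    A participant is flagged iff their mean r deviates from the mean of all
    *other* participants by more than ``n_sd`` times the SD of the others
    (leave-one-out, so an extreme value cannot mask itself).  With fewer than
    3 participants nothing is flagged (warning).
    """
    pids = list(mean_r)
    vals = np.array([mean_r[p] for p in pids], dtype=float)
    if len(pids) < 3:
        logger.warning("flag_heatmap_outliers: need >= 3 participants")
        return {p: False for p in pids}
    flags = {}
    for i, pid in enumerate(pids):
        others = np.delete(vals, i)
        sd = others.std(ddof=1)
        flags[pid] = bool(sd > 0 and abs(vals[i] - others.mean()) > n_sd * sd)
    return flags
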