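"""Core data types and configuration shared by every pipeline stage.

Coordinate convention throughout the package: pixel units, origin at the
top-left of the screen, x increases rightward, y increases downward, screen
bounds half-open ``[0, width) x [0, height)``.  Visual angle is converted at
``px_per_degree`` linear pixels per degree (default 41, a 23-inch 1920x1080
monitor viewed at ~65 cm).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

logger = logging.getLogger("gazepheno")

GROUP_ASD = "ASD"
GROUP_TD = "TD"


@dataclass(frozen=True)
class ScreenGeometry:
    """Stimulus screen geometry in pixels plus the visual-angle conversion."""

    width_px: int = 1920
    height_px: int = 1080
    px_per_degree: float = 41.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.px_per_degree <= 0:
            raise ValueError("px_per_degree must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized half-open bounds test."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= 0) & (x < self.width_px) & (y >= 0) & (y < self.height_px)


@dataclass
class GazeRecording:
    """One participant x episode raw gaze stream.

    ``t`` is seconds from episode start (strictly increasing), ``x``/``y`` are
    pixel coordinates and ``valid`` is the tracker validity flag.  Samples with
    non-finite coordinates are stored but marked invalid.
    """

    participant_id: str
    episode_id: str
    rate_hz: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("sample arrays must have equal length")
        if n and np.any(np.diff(self.t) <= 0):
            raise ValueError(
                f"sample times not strictly increasing for "
                f"{self.participant_id}/{self.episode_id}"
            )
        if n and self.t[0] < 0:
            raise ValueError("sample times must be non-negative")
        # Coordinates that are not finite cannot be on-screen.
        bad = ~(np.isfinite(self.x) & np.isfinite(self.y))
        if bad.any():
            self.valid = self.valid & ~bad

    def __len__(self) -> int:
        return len(self.t)

    def onscreen_mask(self, screen: ScreenGeometry) -> np.ndarray:
        """A sample is on-screen iff valid and inside the screen bounds."""
        with np.errstate(invalid="ignore"):
            inside = screen.contains(np.nan_to_num(self.x, nan=-1.0),
                                     np.nan_to_num(self.y, nan=-1.0))
        return self.valid & inside


@dataclass
class ParticipantMeta:
    """Participant-level metadata used by the group analyses."""

    participant_id: str
    group: str
    site: str = "SiteA"
    familiarity: dict = field(default_factory=dict)  # episode_id -> 1..9
    severity_css: Optional[float] = None
    aq: Optional[float] = None
    age_years: Optional[float] = None
    sex: Optional[str] = None
    fsiq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in (GROUP_ASD, GROUP_TD):
            raise ValueError(f"group must be ASD or TD, got {self.group!r}")
        for ep, r in self.familiarity.items():
            if r is not None and not (1 <= r <= 9):
                raise ValueError(f"familiarity rating {r} for {ep} not in [1, 9]")


# Feature-column names, in the order of the 8-dimensional gaze vector.
FEATURES_8 = (
    "pct_onscreen",
    "pct_face",
    "pct_nonsocial",
    "pct_body",
    "pct_hands",
    "pct_eyes",
    "pct_mouth",
    "mean_heatmap_corr",
)
# Reduced feature set used for classification/clustering and the 4-feature
# fingerprint variant: on-screen, faces, eyes and heatmap correlation.
FEATURES_4 = ("pct_onscreen", "pct_face", "pct_eyes", "mean_heatmap_corr")


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline with their defaults.

    Defaults correspond to the analysis conditions: 24 fps video, 1-s heatmap
    bins, 0.5 deg Gaussian kernel, 1 deg gaze disk, 10,000 resampling
    iterations and a strict >50% missing-data exclusion rule.
    """

    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    frame_rate_fps: float = 24.0
    bin_seconds: float = 1.0
    heatmap_sigma_deg: float = 0.5
    disk_diameter_deg: float = 1.0
    n_boot: int = 10_000
    n_perm: int = 10_000
    epoch_minutes: float = 10.0
    rng_seed: int = 0
    exclusion_missing_fraction: float = 0.5
    fdr_method: str = "bh"
    heatmap_downsample: int = 4

    def __post_init__(self) -> None:
        positive = {
            "frame_rate_fps": self.frame_rate_fps,
            "bin_seconds": self.bin_seconds,
            "heatmap_sigma_deg": self.heatmap_sigma_deg,
            "disk_diameter_deg": self.disk_diameter_deg,
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "epoch_minutes": self.epoch_minutes,
            "heatmap_downsample": self.heatmap_downsample,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not (0 < self.exclusion_missing_fraction < 1):
            raise ValueError("exclusion_missing_fraction must lie in (0, 1)")

    @property
    def sigma_px(self) -> float:
        return self.heatmap_sigma_deg * self.screen.px_per_degree

    @property
    def disk_radius_px(self) -> float:
        return self.disk_diameter_deg * self.screen.px_per_degree / 2.0


_SCREEN_KEYS = {f.name for f in dataclasses.fields(ScreenGeometry)}
_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)} - {"screen"}


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML key-value file.

    Unspecified keys take the defaults; unknown keys raise ``ValueError`` so
    that typos cannot silently fall back to defaults.  ``screen`` may be a
    nested section with ``width_px`` / ``height_px`` / ``px_per_degree``.
    The effective configuration is echoed to the package logger.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    screen_data = data.pop("screen", {}) or {}
    unknown = set(screen_data) - _SCREEN_KEYS
    if unknown:
        raise ValueError(f"unknown screen config keys: {sorted(unknown)}")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    config = PipelineConfig(screen=ScreenGeometry(**screen_data), **data)
    logger.info("effective config: %s", config)
    return config
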