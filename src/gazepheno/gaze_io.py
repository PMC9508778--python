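"""File formats: gaze tables, frame annotations, metadata, heatmap stacks.

All tabular interchange is plain text (TSV/CSV/JSONL); heatmap stacks go to an
HDF5 container.  Reading and writing round-trip exactly on the supported
dialects (times at 1e-6 s precision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GazeRecording, ParticipantMeta, ScreenGeometry, logger

GAZE_COLUMNS = ["participant_id", "episode_id", "t", "x", "y", "valid"]


def read_gaze_table(path, screen: ScreenGeometry | None = None,
                    rate_hz: float = 300.0) -> list[GazeRecording]:
    """Read a gaze table (TSV or CSV by extension) into recordings.

    One :class:`GazeRecording` is produced per (participant, episode) pair, in
    file order.  Rows with non-numeric coordinates are kept but marked invalid
    (with a warning); rows with unparseable times are dropped and logged with
    their line numbers.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze table {path} missing columns: {missing}")

    t = pd.to_numeric(df["t"], errors="coerce")
    bad_t = t.isna()
    if bad_t.any():
        lines = (df.index[bad_t] + 2).tolist()  # header is line 1
        logger.warning("%s: dropped %d rows with bad times (lines %s)",
                       path, bad_t.sum(), lines[:20])
        df = df[~bad_t]
        t = t[~bad_t]

    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    valid = pd.to_numeric(df["valid"], errors="coerce").fillna(0).astype(bool)
    coord_bad = (x.isna() | y.isna()) & valid
    if coord_bad.any():
        logger.warning("%s: %d rows with non-numeric coordinates treated as "
                       "invalid samples", path, int(coord_bad.sum()))
        valid = valid & ~coord_bad

    out = []
    keys = df[["participant_id", "episode_id"]].astype(str)
    for (pid, ep), idx in keys.groupby(
            ["participant_id", "episode_id"], sort=False).groups.items():
        order = np.argsort(t.loc[idx].to_numpy(), kind="stable")
        sel = np.asarray(idx)[order]
        tt = t.loc[sel].to_numpy(dtype=float)
        if len(tt) > 1 and np.any(np.diff(tt) <= 0):
            raise ValueError(f"non-monotone sample times for {pid}/{ep}")
        out.append(GazeRecording(
            participant_id=pid, episode_id=ep, rate_hz=rate_hz,
            t=tt,
            x=x.loc[sel].to_numpy(dtype=float),
            y=y.loc[sel].to_numpy(dtype=float),
            valid=valid.loc[sel].to_numpy(dtype=bool),
        ))
    return out


def write_gaze_table(recordings: Sequence[GazeRecording], path) -> None:
    """Write recordings to a TSV/CSV gaze table (bit-stable for fixed input)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frames = [pd.DataFrame({
        "participant_id": rec.participant_id,
        "episode_id": rec.episode_id,
        "t": np.round(rec.t, 6),
        "x": rec.x,
        "y": rec.y,
        "valid": rec.valid.astype(int),
    }) for rec in recordings]
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=GAZE_COLUMNS))
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")


def write_annotations(frames: Iterable[dict], path) -> None:
    """Write per-frame annotations as JSON Lines (one object per frame)."""
    with open(path, "w") as fh:
        for obj in frames:
            fh.write(json.dumps(obj, separators=(",", ":")) + "\n")


def read_annotations(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


_META_COLS = ["participant_id", "group", "site", "severity_css", "aq",
              "age_years", "sex", "fsiq"]


def write_metadata(metas: Sequence[ParticipantMeta], path) -> None:
    episode_ids = sorted({ep for m in metas for ep in m.familiarity})
    rows = []
    for m in metas:
        row = {c: getattr(m, c) for c in _META_COLS}
        for ep in episode_ids:
            row[f"familiarity_{ep}"] = m.familiarity.get(ep)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> list[ParticipantMeta]:
    df = pd.read_csv(path)
    fam_cols = [c for c in df.columns if c.startswith("familiarity_")]
    metas = []
    for _, row in df.iterrows():
        fam = {}
        for c in fam_cols:
            if pd.notna(row[c]):
                fam[c[len("familiarity_"):]] = int(row[c])
        kw = {}
        for c in _META_COLS:
            v = row.get(c)
            kw[c] = None if pd.isna(v) else v
        metas.append(ParticipantMeta(familiarity=fam, **kw))
    return metas


def save_heatmap_stack(path, grids: np.ndarray, bin_seconds: float,
                       sigma_px: float, downsample: int) -> None:
    """Persist a (bins, h, w) heatmap stack with its grid geometry."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("heatmaps", data=np.asarray(grids, dtype=np.float32),
                               compression="gzip")
        ds.attrs["bin_seconds"] = bin_seconds
        ds.attrs["sigma_px"] = sigma_px
        ds.attrs["downsample"] = downsample


def load_heatmap_stack(path):
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["heatmaps"]
        return np.asarray(ds), dict(ds.attrs)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_dir, command: str, config, seed: int,
                   inputs: Sequence = (), outputs: Sequence = ()) -> Path:
    """Write a run manifest (command, config snapshot, seed, file digests)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": dataclasses.asdict(config) if config is not None else None,
        "seed": seed,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "version": __version__,
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
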