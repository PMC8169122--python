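"""CSV/TIFF input-output and run manifests.

Tracks are stored as two CSVs: one row per (track_id, time_min, red,
green, area_um2, alive) frame and one row per (track_id, event, time_min)
annotation, plus a truth table per track. Images are 16-bit TIFFs with
channel order R, G, B on the last axis; the pixel size travels in the
sidecar manifest (YAML).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from pulsefate.errors import FormatError
from pulsefate.synthetic.fucci import SyntheticTrack

TRACK_COLUMNS = ["track_id", "time_min", "red", "green", "area_um2", "alive"]


def write_tracks(tracks: list[SyntheticTrack], out_dir: str | Path) -> dict:
    """Write a cohort to <out_dir>/{tracks,events,truth}.csv; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame_rows = []
    event_rows = []
    truth_rows = []
    for t in tracks:
        f = t.frames.copy()
        f.insert(0, "track_id", t.track_id)
        frame_rows.append(f)
        for name, tm in t.events:
            event_rows.append((t.track_id, name, tm))
        truth_rows.append(
            (t.track_id, t.truth_fate, t.truth_exposure_phase,
             t.n_divisions_truth)
        )
    paths = {
        "tracks": out / "tracks.csv",
        "events": out / "events.csv",
        "truth": out / "truth.csv",
    }
    pd.concat(frame_rows, ignore_index=True).to_csv(paths["tracks"], index=False)
    pd.DataFrame(event_rows, columns=["track_id", "event", "time_min"]).to_csv(
        paths["events"], index=False
    )
    pd.DataFrame(
        truth_rows,
        columns=["track_id", "truth_fate", "truth_exposure_phase",
                 "n_divisions_truth"],
    ).to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}


def read_tracks(
    tracks_csv: str | Path, events_csv: str | Path | None = None
) -> list[tuple[pd.DataFrame, list[tuple[str, float]]]]:
    """Read (frames, events) pairs, one per track, ordered by track_id."""
    frames = pd.read_csv(tracks_csv)
    missing = [c for c in TRACK_COLUMNS[:4] if c not in frames.columns]
    if missing:
        raise FormatError(f"tracks CSV missing columns: {missing}")
    events = pd.read_csv(events_csv) if events_csv else None
    out = []
    for tid, sub in frames.groupby("track_id", sort=True):
        evs = []
        if events is not None:
            for row in events[events["track_id"] == tid].itertuples():
                evs.append((row.event, float(row.time_min)))
        out.append((sub.drop(columns="track_id").reset_index(drop=True), evs))
    return out


def write_image(path: str | Path, image: np.ndarray, pixel_size_um: float) -> None:
    """Write a 16-bit TIFF; channel order documented in the description tag."""
    tifffile.imwrite(
        str(path),
        np.asarray(image, dtype=np.uint16),
        description=json.dumps(
            {"channel_order": "RGB", "pixel_size_um": pixel_size_um}
        ),
    )


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_manifest(out_dir: str | Path, manifest: dict) -> Path:
    path = Path(out_dir) / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError("config file must contain a mapping")
    return cfg
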