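"""Reading and writing of movies, masks and event tables.

Movies are stored as multi-page TIFF with axis order T[,C],Y,X plus a JSON
sidecar carrying frame rate, pixel pitch and channel names; event tables
and traces are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthetic import Movie

GROUND_TRUTH_COLUMNS = [
    "event_id", "pair_id", "x_px", "y_px", "t_on_s", "mech_class", "cargo_units",
]


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as TCYX TIFF with a ``.json`` metadata sidecar."""
    path = Path(path)
    arr = np.moveaxis(movie.pixels, -1, 1)  # T,H,W,C -> T,C,H,W
    tifffile.imwrite(path, arr.astype(np.float32), metadata={"axes": "TCYX"})
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_pitch_um": movie.pixel_pitch_um,
        "channel_names": list(movie.channel_names),
        "axes": "TCYX",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_movie(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_pitch_um: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> Movie:
    """Read a TIFF movie; metadata comes from the sidecar unless overridden."""
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    rate = frame_rate_hz or meta.get("frame_rate_hz", 10.0)
    pitch = pixel_pitch_um or meta.get("pixel_pitch_um", 0.16)
    names = tuple(channel_names or meta.get("channel_names") or ())
    if arr.ndim == 3:
        arr = arr[:, None]
    if not names:
        names = tuple(f"ch{i}" for i in range(arr.shape[1]))
    return Movie(np.moveaxis(arr, 1, -1), rate, pitch, names)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), mask.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in GROUND_TRUTH_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
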