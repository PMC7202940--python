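"""File formats: TIFF stacks, track CSVs with JSON sidecars, model JSON.

The library API performs no hidden I/O; every artifact written here carries
the seeds and configuration needed to re-run the deterministic stages
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .optics import OpticalModel
from .zcal import Track

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ("frame", "t_s", "x_nm", "y_nm", "z_nm", "amplitude", "flag")


class FormatError(ValueError):
    """Malformed or unsupported input file."""


def write_stack(frames, path) -> None:
    """Write a multi-page 8-bit grayscale TIFF."""
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, frames, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as (n, h, w) uint8.

    16-bit input is rescaled to 0-255 with a warning; RGB or otherwise
    malformed files raise :class:`FormatError`.
    """
    try:
        with tifffile.TiffFile(path) as tf:
            for page in tf.pages:
                if page.samplesperpixel != 1:
                    raise FormatError(
                        f"{path}: RGB/multi-sample TIFF is not supported; "
                        "expected grayscale pages"
                    )
            data = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # truncated / not a TIFF
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got shape {data.shape}"
        )
    if data.dtype == np.uint8:
        return data
    if data.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit input rescaled to 0-255", stacklevel=2)
        return np.rint(data.astype(float) / 65535.0 * 255.0).astype(np.uint8)
    raise FormatError(f"{path}: unsupported dtype {data.dtype}")


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_model(model: OpticalModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(model), fh, indent=1)


def read_model(path) -> OpticalModel:
    with open(path) as fh:
        return OpticalModel(**json.load(fh))


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_track(track: Track, path) -> None:
    """Track CSV plus a JSON sidecar with f_s, seeds and config hash.

    Missing (flagged) coordinates serialize as empty cells.
    """
    df = track.data.copy()
    df.to_csv(path, index=False, float_format="%.9g")
    meta = dict(track.meta)
    meta["f_s"] = track.f_s
    meta["n_frames"] = len(df)
    meta["config_hash"] = config_hash({k: meta[k] for k in sorted(meta)})
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_track(path) -> Track:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing track columns {missing}")
    df["flag"] = df["flag"].fillna("")
    meta = {}
    f_s = np.nan
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
        f_s = float(meta.pop("f_s", np.nan))
    if not np.isfinite(f_s) and len(df) > 1:
        f_s = 1.0 / float(np.mean(np.diff(df["t_s"])))
    return Track(data=df, f_s=f_s, meta=meta)


def write_truth(traj_df: pd.DataFrame, path) -> None:
    traj_df.to_csv(path, index=False, float_format="%.9g")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"frame", "t_s", "x_nm", "y_nm", "z_nm"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: truth CSV needs columns {sorted(needed)}")
    return df
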