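"""Look-up-table baseline tracker.

The traditional camera-based bead tracker: the xy center comes from 1D
autocorrelation of the central line profiles with their mirror image, and
the height from comparing a radial intensity profile against a table of
profiles pre-computed at known heights (quadratic interpolation of the
RMS-difference minimum).  Kept deliberately faithful to the standard recipe
so it can serve as the comparison baseline for the phasor tracker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import correlate

logger = logging.getLogger(__name__)

FLAG_FLAT = "flat_trace"
FLAG_CLAMPED = "z_clamped"


def _mirror_center(trace: np.ndarray) -> tuple[float, str]:
    """Symmetry center of a 1D trace from correlation with its mirror.

    The full zero-padded cross correlation of the mean-removed trace with
    its reverse peaks at lag 2*c (c = symmetry center); the lag is refined
    with a 3-point quadratic vertex, ties toward the lower lag.
    """
    t = np.asarray(trace, dtype=float)
    t = t - t.mean()
    if not np.any(t):
        return (len(trace) - 1) / 2.0, FLAG_FLAT
    cc = correlate(t, t[::-1], mode="full")
    i = int(np.argmax(cc))
    if 0 < i < len(cc) - 1:
        denom = cc[i - 1] + cc[i + 1] - 2.0 * cc[i]
        di = 0.5 * (cc[i - 1] - cc[i + 1]) / denom if denom < 0 else 0.0
    else:
        di = 0.0
    # lag of the correlation max equals twice the center offset
    lag = (i + di) - (len(t) - 1)
    return (len(t) - 1) / 2.0 + lag / 2.0, ""


def lut_locate_xy(image: np.ndarray, n_lines: int = 5):
    """Bead center from mirrored line correlations; (x_px, y_px, flag)
    relative to the ROI center."""
    img = np.asarray(image, dtype=float)
    s = img.shape[0]
    if s < 16:
        raise ValueError("roi_size must be >= 16")
    c = s // 2
    half = n_lines // 2
    row_trace = img[c - half : c - half + n_lines, :].sum(axis=0)
    col_trace = img[:, c - half : c - half + n_lines].sum(axis=1)
    x, fx = _mirror_center(row_trace)
    y, fy = _mirror_center(col_trace)
    if fx or fy:
        return 0.0, 0.0, (fx or fy)
    return x - c, y - c, ""



def radial_profile(image: np.ndarray, center=None) -> np.ndarray:
    """Mean intensity in 1-pixel annuli; length roi_size // 2.

    ``center`` is (x_px, y_px) relative to the ROI center.  Pixel-center
    distances with nearest-bin assignment; empty annuli are filled by linear
    interpolation from their neighbors.
    """
    img = np.asarray(image, dtype=float)
    s = img.shape[0]
    c = s // 2
    cx, cy = (0.0, 0.0) if center is None else (float(center[0]), float(center[1]))
    if abs(cx) > c or abs(cy) > c:
        raise ValueError("center outside the image")
    x = np.arange(s) - c - cx
    y = np.arange(s) - c - cy
    r = np.hypot(x[np.newaxis, :], y[:, np.newaxis])
    n_bins = s // 2
    idx = np.rint(r).astype(int)
    sel = idx < n_bins
    counts = np.bincount(idx[sel], minlength=n_bins)[:n_bins]
    sums = np.bincount(idx[sel], weights=img[sel], minlength=n_bins)[:n_bins]
    prof = np.full(n_bins, np.nan)
    nz = counts > 0
    prof[nz] = sums[nz] / counts[nz]
    if np.any(~nz):
        prof[~nz] = np.interp(np.flatnonzero(~nz), np.flatnonzero(nz), prof[nz])
    return prof


@dataclass
class RadialLUT:
    """Pre-calibrated radial profiles on a strictly increasing z grid."""

    z_grid_nm: np.ndarray
    profiles: np.ndarray = field(repr=False)  # (n_profiles, roi_size // 2)

    def __post_init__(self):
        if len(self.z_grid_nm) < 3:
            raise ValueError("need >= 3 calibration profiles")
        if np.any(np.diff(self.z_grid_nm) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if self.profiles.shape[0] != len(self.z_grid_nm):
            raise ValueError("one profile per z grid point required")


def build_lut(stack, z_true_nm, n_profiles: int = 64) -> RadialLUT:
    """Build a radial-profile LUT from a calibration stack with known z.

    The stack is subsampled to ``n_profiles`` evenly spaced heights; each
    frame is centered with the mirror correlator before the profile is taken.
    """
    z = np.asarray(z_true_nm, dtype=float)
    n = len(stack)
    if n != len(z):
        raise ValueError("stack and z_true lengths differ")
    pick = np.unique(np.linspace(0, n - 1, min(n_profiles, n)).round().astype(int))
    profiles = []
    for i in pick:
        cx, cy, _ = lut_locate_xy(stack[i])
        profiles.append(radial_profile(stack[i], (cx, cy)))
    return RadialLUT(z_grid_nm=z[pick], profiles=np.stack(profiles))


def lut_z(profile: np.ndarray, lut: RadialLUT):
    """Height of a radial profile: quadratic-interpolated minimizer of the
    RMS difference against the LUT grid.  Returns (z_nm, flag)."""
    d = lut.profiles - np.asarray(profile, dtype=float)[np.newaxis]
    rms = np.sqrt(np.mean(d * d, axis=1))
    j = int(np.argmin(rms))
    if rms[j] == 0.0:  # exact node match; the 3-point parabola would drift
        return float(lut.z_grid_nm[j]), ""
    if j in (0, len(rms) - 1):
        return float(lut.z_grid_nm[j]), FLAG_CLAMPED
    denom = rms[j - 1] + rms[j + 1] - 2.0 * rms[j]
    dj = 0.5 * (rms[j - 1] - rms[j + 1]) / denom if denom > 0 else 0.0
    # map the fractional grid index to nm on the local (non-uniform) grid
    if dj >= 0:
        z = lut.z_grid_nm[j] + dj * (lut.z_grid_nm[j + 1] - lut.z_grid_nm[j])
    else:
        z = lut.z_grid_nm[j] + dj * (lut.z_grid_nm[j] - lut.z_grid_nm[j - 1])
    return float(z), ""


def lut_track_video(
    stack,
    lut: RadialLUT,
    f_s: float = 30.0,
    pixel_size_nm: float = 112.0,
    meta: dict | None = None,
):
    """Track a stack with the LUT method; returns a zcal.Track."""
    from .zcal import Track

    rows = []
    for i, frame in enumerate(stack):
        cx, cy, flag = lut_locate_xy(frame)
        z, zflag = lut_z(radial_profile(frame, (cx, cy)), lut)
        rows.append(
            {
                "frame": i,
                "t_s": i / f_s,
                "x_nm": cx * pixel_size_nm,
                "y_nm": cy * pixel_size_nm,
                "z_nm": z,
                "amplitude": np.nan,
                "flag": flag or zflag,
            }
        )
    return Track(data=pd.DataFrame(rows), f_s=f_s, meta=dict(meta or {}))
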