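"""Standard simulation protocols used throughout the package.

These are the canonical conditions for validating the trackers on synthetic
holograms: a 1.0 um paramagnetic bead rendered with the Lorenz-Mie forward
model, imaged at 30 Hz with 112 nm pixels, diffusing weakly (5 nm SD per
axis) around 12 um above focus, plus a piezo-style linear focus ramp for
phase calibration.
"""

from __future__ import annotations

import numpy as np

from .optics import BeadPose, OpticalModel, Trajectory, render_video

#: reference-image periods below 7 px give no distinct correlation peak
MIN_PERIOD_PX = 7.0
MAX_PERIOD_PX = 16.0


def standard_model(**overrides) -> OpticalModel:
    """Optical model of a 1.0 um paramagnetic bead (a = 0.5 um, n_p = 1.9,
    n_m = 1.33, alpha = 1, beta = 54, gamma = 45 px, lambda = 645 nm,
    112 nm pixels)."""
    return OpticalModel(**overrides)


def log_spaced_periods(n: int, lo: float = MIN_PERIOD_PX,
                       hi: float = MAX_PERIOD_PX) -> np.ndarray:
    """n reference periods, logarithmically spaced between lo and hi pixels."""
    return np.geomspace(lo, hi, n)


def standard_trajectory(
    n_frames: int = 3600,
    seed: int | None = None,
    f_s: float = 30.0,
    z_mean_nm: float = 12_000.0,
    xyz_sd_nm: float = 5.0,
    x_mean_nm: float = 0.0,
) -> Trajectory:
    """Bead moving randomly in 3D: dx, dy = 0 +/- 5 nm, dz = 12,000 +/- 5 nm,
    one independent draw per frame (thermal motion of a short stiff tether)."""
    rng = np.random.default_rng(seed)
    xyz = rng.normal(0.0, xyz_sd_nm, size=(n_frames, 3))
    poses = [
        BeadPose(x_mean_nm + dx, dy, z_mean_nm + dz) for dx, dy, dz in xyz
    ]
    return Trajectory(poses, f_s=f_s)


def ramp_trajectory(
    z_lo_nm: float = 4_000.0,
    z_hi_nm: float = 16_000.0,
    n_frames: int = 241,
    f_s: float = 30.0,
) -> Trajectory:
    """Linear focus ramp for phase calibration (bead fixed, focus scanned)."""
    zs = np.linspace(z_lo_nm, z_hi_nm, n_frames)
    return Trajectory([BeadPose(0.0, 0.0, z) for z in zs], f_s=f_s)


def render_calibration_stack(
    model: OpticalModel | None = None,
    roi_size: int = 150,
    z_lo_nm: float = 4_000.0,
    z_hi_nm: float = 16_000.0,
    n_frames: int = 241,
    quantize: bool = True,
):
    """Render a calibration ramp; returns (stack, z_true_nm)."""
    model = model or standard_model()
    traj = ramp_trajectory(z_lo_nm, z_hi_nm, n_frames)
    stack = render_video(model, traj, roi_size, quantize=quantize)
    return stack, np.array([p.z_nm for p in traj.poses])
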