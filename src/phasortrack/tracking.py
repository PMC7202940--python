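"""Scikit-learn-style tracker estimators.

Both trackers follow the fit/predict contract: ``fit(X, y)`` takes a
calibration stack ``X`` of shape (n_frames, s, s) with known heights ``y``
(nm) — a piezo focus ramp — and ``predict(X)`` converts a stack of
holograms into a per-frame coordinate table.  They compose with sklearn
tooling (``get_params``/``set_params``, cloning) and wrap the functional
layers in :mod:`phasortrack.phasor`, :mod:`phasortrack.zcal` and
:mod:`phasortrack.lut`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import lut as _lut
from . import zcal as _zcal
from .phasor import build_reference_set
from .protocols import log_spaced_periods


def _check_stack(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[np.newaxis]
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError("X must be a stack of square frames (n, s, s)")
    return X


class PhasorTracker(BaseEstimator):
    """3D phasor tracker: FFT cross correlation with single-frequency
    references for xy, multi-frequency correlation phase for z.

    Parameters
    ----------
    n_periods : number of reference periods, log-spaced between 7 and 16 px
        (ignored if ``periods`` is given).  Two is the minimum for the 2 pi
        disambiguation; accuracy keeps improving up to ~10-15.
    periods : explicit reference periods in pixels.
    rel_bandwidth : bandpass SD as a fraction of the reference frequency.
    poly_order : order of the per-period phase->z calibration polynomial.
    fit_range : (z_lo, z_hi) nm calibration range; default the top 10 um of
        the ramp.
    phase_window : side (px) of the amplitude-weighted phase window.
    n_multiply : number of amplitude maps multiplied for the xy peak.
    window_halfwidth_nm : half-width of the frame-to-frame z search window.
    pixel_size_nm, f_s : camera geometry and framerate.

    Attributes
    ----------
    reference_set_ : cached frequency-domain references.
    calibration_ : fitted :class:`~phasortrack.zcal.PhaseCalibration`.
    sigma_res_nm_ : per-period calibration residual SD (nm).
    focus_nm_ : focus position from the linear-asymptote intersection.
    """

    def __init__(
        self,
        n_periods: int = 5,
        periods=None,
        rel_bandwidth: float = 0.2,
        poly_order: int = 5,
        fit_range=None,
        phase_window: int = 10,
        n_multiply: int | None = None,
        window_halfwidth_nm: float = 1500.0,
        pixel_size_nm: float = 112.0,
        f_s: float = 30.0,
    ):
        self.n_periods = n_periods
        self.periods = periods
        self.rel_bandwidth = rel_bandwidth
        self.poly_order = poly_order
        self.fit_range = fit_range
        self.phase_window = phase_window
        self.n_multiply = n_multiply
        self.window_halfwidth_nm = window_halfwidth_nm
        self.pixel_size_nm = pixel_size_nm
        self.f_s = f_s

    def _periods(self):
        if self.periods is not None:
            return np.asarray(self.periods, dtype=float)
        return log_spaced_periods(self.n_periods)

    def fit(self, X, y):
        """Calibrate phase->height from a focus ramp with known heights."""
        X = _check_stack(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("one known height per calibration frame required")
        self.roi_size_ = X.shape[1]
        self.reference_set_ = build_reference_set(
            self.roi_size_, self._periods(), self.rel_bandwidth,
        )
        self.calibration_ = _zcal.calibrate_stack(
            X, y, self.reference_set_, order=self.poly_order,
            fit_range=self.fit_range, phase_window=self.phase_window,
        )
        self.sigma_res_nm_ = self.calibration_.sigma_res_nm
        self.focus_nm_ = self.calibration_.focus_nm
        return self

    def predict(self, X, z_window=None) -> pd.DataFrame:
        """Track a stack; returns a frame-indexed coordinate table (nm)."""
        check_is_fitted(self, "calibration_")
        X = _check_stack(X)
        track = _zcal.track_video(
            X, self.reference_set_, self.calibration_, f_s=self.f_s,
            z_window=z_window, pixel_size_nm=self.pixel_size_nm,
            n_multiply=self.n_multiply, phase_window=self.phase_window,
            window_halfwidth_nm=self.window_halfwidth_nm,
        )
        return track.data

    def track(self, X, z_window=None, meta=None) -> "_zcal.Track":
        """Like predict, but returns the full Track carrier."""
        check_is_fitted(self, "calibration_")
        X = _check_stack(X)
        return _zcal.track_video(
            X, self.reference_set_, self.calibration_, f_s=self.f_s,
            z_window=z_window, pixel_size_nm=self.pixel_size_nm,
            n_multiply=self.n_multiply, phase_window=self.phase_window,
            window_halfwidth_nm=self.window_halfwidth_nm, meta=meta,
        )


class LUTTracker(BaseEstimator):
    """Look-up-table baseline tracker (mirror-correlation xy, radial-profile
    RMS z with quadratic interpolation)."""

    def __init__(self, n_profiles: int = 64, pixel_size_nm: float = 112.0,
                 f_s: float = 30.0):
        self.n_profiles = n_profiles
        self.pixel_size_nm = pixel_size_nm
        self.f_s = f_s

    def fit(self, X, y):
        X = _check_stack(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("one known height per calibration frame required")
        self.roi_size_ = X.shape[1]
        self.lut_ = _lut.build_lut(X, y, n_profiles=self.n_profiles)
        return self

    def predict(self, X) -> pd.DataFrame:
        check_is_fitted(self, "lut_")
        X = _check_stack(X)
        return _lut.lut_track_video(
            X, self.lut_, f_s=self.f_s, pixel_size_nm=self.pixel_size_nm,
        ).data
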