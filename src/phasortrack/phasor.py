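"""Per-frame FFT-phasor computation (the core of 3D phasor tracking).

A hologram is cross-correlated, through FFTs, with computer-generated
complex reference images that each contain a single radial spatial period
k_n.  The product of two correlation amplitude maps peaks sharply at the
bead's xy position; the correlation phase at that peak encodes the bead
height.  All correlations are cyclic (no zero-padding), so a bead shifted
out of the ROI wraps around — the robustness benchmark exercises exactly
this behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .protocols import MIN_PERIOD_PX

#: flags attached to per-frame fixes
FLAG_OK = ""
FLAG_EDGE = "edge"
FLAG_NO_BEAD = "no_bead"
FLAG_WINDOW_CLIPPED = "window_clipped"


@dataclass
class ReferenceSet:
    """Precomputed single-frequency reference images for one ROI size.

    For each period k_n the cache holds conj(FFT2(I_n)) * f_B with
    I_n(r) = f_win(r) exp(2 pi i r / k_n), f_win a Hann window over the ROI
    and f_B a Gaussian annulus in radial spatial frequency centered on
    1 / k_n cycles/pixel with SD ``w_n = rel_bandwidth / k_n``.
    """

    roi_size: int
    periods: np.ndarray
    rel_bandwidth: float
    refs_f: np.ndarray = field(repr=False)  # (n_periods, s, s) complex
    references: np.ndarray = field(repr=False)  # (n_periods, s, s) complex

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def bandwidths(self) -> np.ndarray:
        """Per-period bandpass SD in cycles/pixel."""
        return self.rel_bandwidth / np.asarray(self.periods)


def spatial_window(s: int) -> np.ndarray:
    """Radial Hann window over the ROI: (cos(2 pi r / s) + 1)/2 for r < s/2."""
    c = s // 2
    x = np.arange(s) - c
    r = np.hypot(x[np.newaxis, :], x[:, np.newaxis])
    w = 0.5 * (np.cos(2.0 * np.pi * r / s) + 1.0)
    return np.where(r < s / 2.0, w, 0.0)


def reference_image(s: int, period_px: float) -> np.ndarray:
    """Complex single-frequency reference I_n(r) = f_win(r) e^{2 pi i r/k_n}."""
    c = s // 2
    x = np.arange(s) - c
    r = np.hypot(x[np.newaxis, :], x[:, np.newaxis])
    return spatial_window(s) * np.exp(2.0j * np.pi * r / period_px)


def radial_bandpass(s: int, period_px: float, w: float) -> np.ndarray:
    """Gaussian annulus exp(-(q - 1/k_n)^2 / (2 w^2)) on radial frequency q,
    laid out in unshifted FFT order."""
    f = np.fft.fftfreq(s)
    q = np.hypot(f[np.newaxis, :], f[:, np.newaxis])
    return np.exp(-((q - 1.0 / period_px) ** 2) / (2.0 * w**2))


def build_reference_set(
    roi_size: int,
    periods,
    rel_bandwidth: float = 0.2,
) -> ReferenceSet:
    """Construct and cache the frequency-domain references for each period.

    The bandpass SD for period k_n is ``rel_bandwidth / k_n`` (20% relative
    width by default), which keeps neighboring log-spaced periods between 7
    and 16 px largely non-overlapping.
    """
    s = int(roi_size)
    periods = np.atleast_1d(np.asarray(periods, dtype=float))
    if np.any(periods >= s / 2):
        raise ValueError("reference periods must be < roi_size / 2")
    if np.any(np.diff(periods) <= 0):
        raise ValueError("periods must be strictly increasing")
    if np.any(periods < MIN_PERIOD_PX):
        warnings.warn(
            f"periods below {MIN_PERIOD_PX} px rarely yield a distinct "
            "correlation peak", stacklevel=2,
        )
    refs = np.stack([reference_image(s, k) for k in periods])
    refs_f = np.stack(
        [
            np.conj(np.fft.fft2(ref)) * radial_bandpass(s, k, rel_bandwidth / k)
            for ref, k in zip(refs, periods)
        ]
    )
    return ReferenceSet(
        roi_size=s, periods=periods, rel_bandwidth=rel_bandwidth,
        refs_f=refs_f, references=refs,
    )


def cross_correlate(image: np.ndarray, refs: ReferenceSet) -> np.ndarray:
    """Band-passed cyclic cross correlation with every reference image.

    Returns a complex (n_periods, s, s) array, fftshifted so that zero lag
    sits at pixel (s//2, s//2): a bead displaced by (dx, dy) pixels from the
    ROI center produces an amplitude peak at (s//2 + dy, s//2 + dx).
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (refs.roi_size, refs.roi_size):
        raise ValueError(
            f"image shape {image.shape} does not match ROI size {refs.roi_size}"
        )
    f_img = np.fft.fft2(image)
    cc = np.fft.ifft2(refs.refs_f * f_img[np.newaxis], axes=(-2, -1))
    return np.fft.fftshift(cc, axes=(-2, -1))


@dataclass
class PhasorFix:
    """Sub-pixel xy fix plus per-period correlation phases for one frame."""

    x_px: float
    y_px: float
    peak_amplitude: float
    phases: np.ndarray
    amplitudes: np.ndarray
    flag: str = FLAG_OK


def locate_xy(cc: np.ndarray, n_multiply: int | None = None,
              window_half_px: int = 16, threshold_frac: float = 0.5):
    """Sub-pixel bead position from the product of correlation amplitudes.

    The amplitude maps with the most distinct peaks (largest max/median
    ratio) are multiplied elementwise — ``n_multiply`` of them, default
    min(5, n_periods) — so that periods whose correlation has died away at
    the current defocus cannot scramble the product.  The argmax is refined
    by the centroid of the product above ``threshold_frac`` of its maximum,
    inside a ``window_half_px`` neighborhood: the correlation peak is many
    pixels wide and mirror-symmetric about the bead, so the thresholded
    centroid is both sub-pixel accurate and strongly noise-averaging (a
    3-point parabola through the nearly flat peak top would amplify pixel
    noise instead).  Returns (x_px, y_px, peak_amplitude, flag) with x, y
    relative to the ROI center; ties at the argmax break toward the
    smallest row-major index.
    """
    cc = cc[np.newaxis] if cc.ndim == 2 else cc
    amps = np.abs(cc)
    if not amps.any():
        return 0.0, 0.0, 0.0, FLAG_NO_BEAD
    n_sel = min(5, len(amps)) if n_multiply is None else min(n_multiply, len(amps))
    if len(amps) > n_sel:
        med = np.median(amps, axis=(1, 2))
        ratio = amps.max(axis=(1, 2)) / np.where(med > 0, med, np.inf)
        keep = np.sort(np.argsort(ratio)[::-1][:n_sel])
        amps = amps[keep]
    prod = np.prod(amps, axis=0)
    s = prod.shape[0]
    c = s // 2
    iy, ix = np.unravel_index(int(np.argmax(prod)), prod.shape)
    peak = float(prod[iy, ix])
    flag = FLAG_OK
    y0, y1 = iy - window_half_px, iy + window_half_px + 1
    x0, x1 = ix - window_half_px, ix + window_half_px + 1
    if y0 < 0 or x0 < 0 or y1 > s or x1 > s:
        flag = FLAG_EDGE  # clipped neighborhood biases the centroid
        y0, y1 = max(y0, 0), min(y1, s)
        x0, x1 = max(x0, 0), min(x1, s)
    patch = prod[y0:y1, x0:x1]
    w = np.maximum(patch - threshold_frac * peak, 0.0)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    x_hat = float(np.sum(w * xs) / w.sum())
    y_hat = float(np.sum(w * ys) / w.sum())
    return x_hat - c, y_hat - c, peak, flag


def extract_phase(cc_n: np.ndarray, peak_xy, window: int = 10):
    """Amplitude-weighted correlation phase in a window around the peak.

    The complex correlation is averaged with weights |CC_n| over a
    ``window x window`` pixel box centered on the rounded peak, and the
    argument of the sum is returned — circular averaging, so phases near
    +/- pi do not cancel.  Returns (phi_n, mean_amplitude, flag).
    """
    s = cc_n.shape[0]
    c = s // 2
    ix = int(round(peak_xy[0])) + c
    iy = int(round(peak_xy[1])) + c
    half = window // 2
    y0, y1 = iy - half, iy - half + window
    x0, x1 = ix - half, ix - half + window
    flag = FLAG_OK
    if y0 < 0 or x0 < 0 or y1 > s or x1 > s:
        flag = FLAG_WINDOW_CLIPPED
        y0, y1 = max(y0, 0), min(y1, s)
        x0, x1 = max(x0, 0), min(x1, s)
    patch = cc_n[y0:y1, x0:x1]
    w = np.abs(patch)
    z = np.sum(w * patch)
    amp = float(w.mean()) if w.size else 0.0
    if z == 0:
        return 0.0, amp, FLAG_NO_BEAD
    phi = float(np.angle(z))
    if phi <= -np.pi:  # normalize to (-pi, pi]
        phi += 2.0 * np.pi
    return phi, amp, flag


def analyze_frame(
    image: np.ndarray,
    refs: ReferenceSet,
    n_multiply: int | None = None,
    phase_window: int = 10,
) -> PhasorFix:
    """Full per-frame phasor computation: correlate, locate, extract phases."""
    cc = cross_correlate(image, refs)
    x, y, peak, flag = locate_xy(cc, n_multiply=n_multiply)
    phases = np.empty(refs.n_periods)
    amps = np.empty(refs.n_periods)
    for i in range(refs.n_periods):
        phi, amp, pflag = extract_phase(cc[i], (x, y), window=phase_window)
        phases[i] = phi
        amps[i] = amp
        if pflag and not flag:
            flag = pflag
    return PhasorFix(
        x_px=x, y_px=y, peak_amplitude=peak, phases=phases,
        amplitudes=amps, flag=flag,
    )
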