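"""Tracking-accuracy metrics: PSD, plateau fitting, drift removal.

Accuracy is quantified as the high-frequency plateau of the power spectral
density of a position (or tracking-error) trace, sigma^2/f_s in nm^2/Hz.
The density convention is the two-sided one reported at positive
frequencies — the convention under which white position noise of standard
deviation sigma sampled at f_s has a flat density sigma^2/f_s, and the
tracking SD implied by a plateau P is sqrt(P * f_s).  (A one-sided density
would carry an extra factor of 2 and break that arithmetic.)  Parseval then
reads 2 * sum(P * df) = var(trace), with the Nyquist bin counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, welch


@dataclass
class PSDResult:
    """Two-sided power density at positive frequencies, (0, f_s/2]."""

    freq_hz: np.ndarray
    power: np.ndarray  # nm^2/Hz
    f_s: float

    @property
    def df(self) -> float:
        return float(self.freq_hz[1] - self.freq_hz[0]) if len(self.freq_hz) > 1 \
            else self.f_s / 2.0

    def variance(self) -> float:
        """Total variance implied by the spectrum (Parseval)."""
        w = np.full(len(self.power), 2.0)
        if len(self.power) and np.isclose(self.freq_hz[-1], self.f_s / 2.0):
            w[-1] = 1.0  # Nyquist bin is its own mirror image
        return float(np.sum(w * self.power) * self.df)


def psd(trace, f_s: float, welch_segments: int | None = None) -> PSDResult:
    """Mean-removed periodogram of a position trace.

    ``welch_segments`` switches to Welch averaging (that many segments, 50%
    overlap) to reduce plateau variance; the plain periodogram is the
    default.  Missing values must be excluded upstream.
    """
    x = np.asarray(trace, dtype=float)
    if len(x) < 256:
        raise ValueError("need >= 256 samples for a PSD")
    if np.any(~np.isfinite(x)):
        raise ValueError("trace contains missing values; drop them upstream")
    x = x - x.mean()
    if welch_segments:
        nper = int(2 * len(x) / (welch_segments + 1))
        f, p_one = welch(x, fs=f_s, nperseg=nper)
        keep = f > 0
        return PSDResult(freq_hz=f[keep], power=p_one[keep] / 2.0, f_s=f_s)
    n = len(x)
    xf = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / f_s)
    p = np.abs(xf) ** 2 / (n * f_s)  # two-sided density
    return PSDResult(freq_hz=f[1:], power=p[1:], f_s=f_s)


def plateau(res: PSDResult, f_min: float = 5.0) -> float:
    """Horizontal-line fit (mean density) over f > f_min, in nm^2/Hz.

    5 Hz is the standard cut for 30 Hz imaging; 2 Hz is sometimes preferred
    when low-frequency drift is mild.
    """
    if f_min >= res.f_s / 2.0:
        raise ValueError("f_min must be below the Nyquist frequency")
    sel = res.freq_hz > f_min
    return float(np.mean(res.power[sel]))


def plateau_to_sd(plateau_nm2_hz: float, f_s: float) -> float:
    """Tracking SD implied by a PSD plateau: sigma = sqrt(plateau * f_s)."""
    if plateau_nm2_hz < 0:
        raise ValueError("plateau must be non-negative")
    return float(np.sqrt(plateau_nm2_hz * f_s))


def trace_plateau(trace, f_s: float, f_min: float = 5.0) -> float:
    """Convenience: plateau of a trace's PSD, NaNs dropped."""
    x = np.asarray(trace, dtype=float)
    x = x[np.isfinite(x)]
    return plateau(psd(x, f_s), f_min=f_min)


def remove_common_mode(traces, f_s: float, cutoff_hz: float = 1.0):
    """Subtract the low-pass-filtered across-bead mean trace.

    ``traces`` is (n_beads, n_samples) for one axis.  The mean trace is
    filtered with a zero-phase 4th-order Butterworth low-pass at
    ``cutoff_hz`` (forward-backward, so the subtracted common mode has no
    phase lag) and removed from every bead.  Returns (corrected, common).
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 aligned traces to estimate a common mode")
    mean_trace = x.mean(axis=0)
    b, a = butter(4, cutoff_hz / (f_s / 2.0), btype="low")
    common = filtfilt(b, a, mean_trace)
    return x - common[np.newaxis, :], common
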