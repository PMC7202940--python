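"""Phase-to-height calibration and multi-frequency z disambiguation.

The correlation phase of each reference period grows monotonically (and, far
from focus, almost linearly) with bead height.  A calibration ramp — the
focus scanned linearly through a known z range — yields, after unwrapping,
one smooth phi_n(z) curve per period, which is fitted with a polynomial and
inverted numerically.  At track time a measured phase is only known modulo
2 pi; candidate heights spaced by one phase period are enumerated for every
reference period inside a z window, and the candidate combination whose
members agree best (smallest sample variance) is averaged into the final z.

The near-linear law phi_n(z) ~ c * k_n^e * z anchors the focus estimate: the
per-period linear asymptotes extrapolate to a common intersection at the
focal plane.  The exponent e is measured from the fitted slopes rather than
assumed; with these optics it comes out close to -2 (finer reference rings
pick up the hologram's phase faster).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phasor import FLAG_OK, ReferenceSet, analyze_frame

logger = logging.getLogger(__name__)

FLAG_UNTRACKABLE = "untrackable"
FLAG_LOW_CONFIDENCE = "low_confidence"


def unwrap_ramp(phases) -> np.ndarray:
    """Remove 2 pi jumps from an ordered phase sequence.

    Adds integer multiples of 2 pi so that successive differences lie in
    (-pi, pi]; the first element is unchanged.  Assumes true increments are
    below pi in magnitude, which holds on a calibration ramp sampled finely
    enough.
    """
    phases = np.asarray(phases, dtype=float)
    out = np.unwrap(phases)
    jumps = np.abs(np.diff(out))
    if np.any(jumps > 0.9 * np.pi):
        logger.warning(
            "large phase increments (max %.2f rad) during unwrapping; "
            "ramp may be undersampled", float(jumps.max()),
        )
    return out


@dataclass
class PhaseCalibration:
    """Per-period unwrapped phase->z polynomials plus inverse interpolants.

    ``coeffs[i]`` are polynomial coefficients (power basis, in the scaled
    variable u = (z - mid) / half_span for conditioning) for period
    ``periods[i]``; phi(z) is strictly monotonic on [z_lo, z_hi] for every
    usable period.
    """

    periods: np.ndarray
    coeffs: list
    z_lo_nm: float
    z_hi_nm: float
    order: int
    focus_nm: float = np.nan
    linear_coeff: float = np.nan
    slope_exponent: float = np.nan
    sigma_res_nm: np.ndarray = field(default_factory=lambda: np.array([]))
    source_indices: np.ndarray | None = None  # columns of the phase array used
    grid_n: int = 4096
    _z_grid: np.ndarray = field(default=None, repr=False)
    _phi_grid: np.ndarray = field(default=None, repr=False)  # (n_periods, grid_n)
    _sign: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.source_indices is None:
            self.source_indices = np.arange(len(self.periods))
        if self._z_grid is None:
            self._build_grid()

    def _scale(self, z):
        mid = 0.5 * (self.z_lo_nm + self.z_hi_nm)
        half = 0.5 * (self.z_hi_nm - self.z_lo_nm)
        return (np.asarray(z, dtype=float) - mid) / half

    def phase(self, period_index: int, z_nm) -> np.ndarray:
        """Unwrapped calibrated phase phi_n(z)."""
        return np.polyval(self.coeffs[period_index][::-1], self._scale(z_nm))

    def _build_grid(self):
        self._z_grid = np.linspace(self.z_lo_nm, self.z_hi_nm, self.grid_n)
        self._phi_grid = np.stack(
            [self.phase(i, self._z_grid) for i in range(len(self.periods))]
        )
        dphi = np.diff(self._phi_grid, axis=1)
        sign = np.zeros(len(self.periods))
        for i, d in enumerate(dphi):
            if np.all(d > 0):
                sign[i] = 1.0
            elif np.all(d < 0):
                sign[i] = -1.0
            else:
                raise ValueError(
                    f"calibrated phase for period {self.periods[i]:.2f} px is "
                    "not monotonic on the calibration range"
                )
        self._sign = sign

    def z_of_phase(self, period_index: int, phi_unwrapped) -> np.ndarray:
        """Monotone inverse interpolant z(phi_n)."""
        phi = self._sign[period_index] * self._phi_grid[period_index]
        return np.interp(
            self._sign[period_index] * np.asarray(phi_unwrapped, dtype=float),
            phi, self._z_grid,
        )

    def candidates(self, period_index: int, phi_wrapped: float,
                   z_window) -> np.ndarray:
        """All heights in ``z_window`` whose phase is phi mod 2 pi."""
        z0 = max(float(z_window[0]), self.z_lo_nm)
        z1 = min(float(z_window[1]), self.z_hi_nm)
        if z1 <= z0:
            return np.array([])
        lo, hi = sorted(
            (float(self.phase(period_index, z0)), float(self.phase(period_index, z1)))
        )
        m0 = int(np.ceil((lo - phi_wrapped) / (2.0 * np.pi)))
        m1 = int(np.floor((hi - phi_wrapped) / (2.0 * np.pi)))
        if m1 < m0:
            return np.array([])
        phis = phi_wrapped + 2.0 * np.pi * np.arange(m0, m1 + 1)
        return np.sort(self.z_of_phase(period_index, phis))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "periods": self.periods.tolist(),
            "coeffs": [np.asarray(c).tolist() for c in self.coeffs],
            "z_lo_nm": self.z_lo_nm,
            "z_hi_nm": self.z_hi_nm,
            "order": self.order,
            "focus_nm": float(self.focus_nm),
            "linear_coeff": float(self.linear_coeff),
            "slope_exponent": float(self.slope_exponent),
            "sigma_res_nm": np.asarray(self.sigma_res_nm).tolist(),
            "source_indices": np.asarray(self.source_indices).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseCalibration":
        return cls(
            periods=np.asarray(d["periods"], dtype=float),
            coeffs=[np.asarray(c, dtype=float) for c in d["coeffs"]],
            z_lo_nm=float(d["z_lo_nm"]),
            z_hi_nm=float(d["z_hi_nm"]),
            order=int(d["order"]),
            focus_nm=float(d.get("focus_nm", np.nan)),
            linear_coeff=float(d.get("linear_coeff", np.nan)),
            slope_exponent=float(d.get("slope_exponent", np.nan)),
            sigma_res_nm=np.asarray(d.get("sigma_res_nm", []), dtype=float),
            source_indices=(
                np.asarray(d["source_indices"], dtype=int)
                if "source_indices" in d else None
            ),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PhaseCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _focus_from_asymptotes(z, phi_per_period, z_cut):
    """Least-squares common intersection of the per-period linear asymptotes.

    With lines phi_n = s_n z + b_n fitted above ``z_cut``, the focus is the z
    minimizing the across-period variance of the line values — a closed-form
    minimum of a quadratic in z.
    """
    slopes, offsets = [], []
    sel = z >= z_cut
    for phi in phi_per_period:
        s_n, b_n = np.polyfit(z[sel], phi[sel], 1)
        slopes.append(s_n)
        offsets.append(b_n)
    slopes = np.asarray(slopes)
    offsets = np.asarray(offsets)
    var_s = np.var(slopes)
    if var_s == 0:
        return np.nan, slopes
    z0 = -np.cov(slopes, offsets, bias=True)[0, 1] / var_s
    return float(z0), slopes


def calibrate(
    z_true_nm,
    phases,
    periods,
    order: int = 5,
    fit_range=None,
) -> PhaseCalibration:
    """Fit per-period phase->z polynomials from a calibration ramp.

    Parameters
    ----------
    z_true_nm : known heights of the ramp, monotonic, in nm.
    phases : (n_frames, n_periods) wrapped phases measured on the ramp.
    periods : reference periods in pixels (for the linear-law diagnostics).
    order : polynomial order (5 captures the near-focus curvature over a
        10 um range; orders beyond ~10 stop improving tracking accuracy).
    fit_range : (z_lo, z_hi) nm; defaults to focus + 5 um .. + 15 um taken
        as the upper 10 um of the ramp.
    """
    z = np.asarray(z_true_nm, dtype=float)
    phases = np.asarray(phases, dtype=float)
    periods = np.asarray(periods, dtype=float)
    if phases.ndim != 2 or phases.shape[0] != len(z):
        raise ValueError("phases must be (n_frames, n_periods)")
    if np.any(np.diff(z) <= 0):
        order_idx = np.argsort(z)
        z = z[order_idx]
        phases = phases[order_idx]
        if np.any(np.diff(z) <= 0):
            raise ValueError("z_true must be strictly monotonic")
    if fit_range is None:
        fit_range = (max(z[0], z[-1] - 10_000.0), z[-1])
    z_lo, z_hi = float(fit_range[0]), float(fit_range[1])
    sel = (z >= z_lo) & (z <= z_hi)
    if sel.sum() < 10 * (order + 1):
        raise ValueError(
            f"need >= {10 * (order + 1)} ramp samples in the fit range, "
            f"got {int(sel.sum())}"
        )

    mid = 0.5 * (z_lo + z_hi)
    half = 0.5 * (z_hi - z_lo)
    u = (z[sel] - mid) / half
    coeffs, sig_res, unwrapped_all = [], [], []
    usable = []
    u_dense = np.linspace(-1.0, 1.0, 1024)

    def _monotone_fit(phi_sel):
        """Highest-order monotone polynomial fit, falling back towards a
        line when phase noise makes high-order fits wiggle."""
        for p in range(order, 0, -1):
            c = np.polyfit(u, phi_sel, p)[::-1]  # ascending powers
            dcheck = np.polynomial.polynomial.polyval(
                u_dense, np.polynomial.polynomial.polyder(c)
            )
            if np.all(dcheck > 0) or np.all(dcheck < 0):
                return c, p
        return None, 0

    for i in range(phases.shape[1]):
        phi_u = unwrap_ramp(phases[:, i])
        c, used_order = _monotone_fit(phi_u[sel])
        if c is None:
            logger.warning(
                "period %.2f px: no monotone phase-height fit exists; "
                "dropping from calibration", periods[i],
            )
            continue
        if used_order < order:
            logger.info(
                "period %.2f px: order reduced to %d to keep the fitted "
                "curve monotonic", periods[i], used_order,
            )
        fit = np.polyval(c[::-1], u)
        resid = phi_u[sel] - fit
        # local slope in rad/nm converts the phase residual into nm
        dcoef = np.polynomial.polynomial.polyder(c)
        slope = np.polynomial.polynomial.polyval(u, dcoef) / half
        sig_res.append(float(np.std(resid / np.abs(slope))))
        coeffs.append(c)
        unwrapped_all.append(phi_u)
        usable.append(i)
    if len(usable) < 2:
        raise ValueError("fewer than 2 periods produced a usable calibration")

    # focus + linear-law diagnostics from the upper part of the ramp
    z_cut = z_lo + 0.6 * (z_hi - z_lo)
    focus, slopes = _focus_from_asymptotes(
        z[sel], [p[sel] for p in unwrapped_all], z_cut,
    )
    k_used = periods[usable]
    log_s = np.log(np.abs(slopes))
    exponent, log_c = np.polyfit(np.log(k_used), log_s, 1)
    cal = PhaseCalibration(
        periods=k_used,
        coeffs=coeffs,
        z_lo_nm=z_lo,
        z_hi_nm=z_hi,
        order=order,
        focus_nm=focus,
        linear_coeff=float(np.exp(log_c)),
        slope_exponent=float(exponent),
        sigma_res_nm=np.asarray(sig_res),
        source_indices=np.asarray(usable, dtype=int),
    )
    return cal


def measure_ramp(stack, refs: ReferenceSet, phase_window: int = 10,
                 n_multiply: int | None = None):
    """Run the phasor stage over a calibration stack.

    Returns (phases (n, n_periods), xy (n, 2) in px, amplitudes).
    """
    n = len(stack)
    phases = np.empty((n, refs.n_periods))
    amps = np.empty((n, refs.n_periods))
    xy = np.empty((n, 2))
    for i, frame in enumerate(stack):
        fix = analyze_frame(frame, refs, n_multiply=n_multiply,
                            phase_window=phase_window)
        phases[i] = fix.phases
        amps[i] = fix.amplitudes
        xy[i] = (fix.x_px, fix.y_px)
    return phases, xy, amps


def calibrate_stack(stack, z_true_nm, refs: ReferenceSet, order: int = 5,
                    fit_range=None, phase_window: int = 10) -> PhaseCalibration:
    """Phase measurement + polynomial calibration in one call."""
    phases, _, _ = measure_ramp(stack, refs, phase_window=phase_window)
    return calibrate(z_true_nm, phases, refs.periods, order=order,
                     fit_range=fit_range)


def resolve_z(
    phases,
    cal: PhaseCalibration,
    z_window,
    amplitudes=None,
    confidence_sd_nm: float = 300.0,
):
    """Resolve the 2 pi ambiguity using all reference periods.

    Enumerates, per period, every candidate height in ``z_window`` whose
    calibrated phase matches the measurement modulo 2 pi; every candidate in
    turn anchors a combination built from the nearest candidate of each other
    period, and the combination with the smallest sample variance wins (ties
    break toward the lowest mean).  When ``amplitudes`` is given, the winning
    combination is averaged with inverse-variance weights
    w_n = (amplitude_n * |dphi_n/dz|)^2: the phase noise of period n scales
    inversely with its correlation amplitude (which varies strongly with
    defocus — a period whose correlation has died away carries no height
    information), and a phase error converts to height through the local
    calibration slope.  Without amplitudes the combination is averaged
    uniformly.  Returns (z_nm, flag, chosen_candidates).
    """
    phases = np.asarray(phases, dtype=float)
    n_periods = len(cal.periods)
    if phases.shape[0] != n_periods:
        raise ValueError("one phase per calibrated period required")
    if amplitudes is not None:
        weights = np.asarray(amplitudes, dtype=float)
        if weights.shape != phases.shape or np.any(weights < 0):
            raise ValueError("amplitudes must be non-negative, one per period")
        if weights.sum() == 0:
            weights = np.ones(n_periods)
    else:
        weights = np.ones(n_periods)
    weights = weights / weights.sum()
    cand = [cal.candidates(i, float(phases[i]), z_window) for i in range(n_periods)]
    # a period whose measured phase has no match inside the window carries no
    # usable height information there (e.g. its correlation has died away at
    # this defocus); it drops out of the combination
    usable = [i for i, c in enumerate(cand) if len(c) > 0]
    if len(usable) == 0 or (len(usable) < 2 and n_periods > 1):
        return np.nan, FLAG_UNTRACKABLE, None
    cand = [cand[i] for i in usable]
    weights = weights[usable]
    if weights.sum() == 0:
        weights = np.ones(len(usable))
    weights = weights / weights.sum()
    if len(cand) == 1:
        return float(cand[0][0]), FLAG_OK, cand[0]
    best = None
    for anchor_list in cand:
        for z_a in anchor_list:
            picks = np.array(
                [c[np.argmin(np.abs(c - z_a))] for c in cand]
            )
            var = float(np.var(picks))
            mean = float(np.mean(picks))
            key = (var, mean)
            if best is None or key < best[0]:
                best = (key, picks)
    (var, _), picks = best
    if amplitudes is not None:
        z_ref = float(np.mean(picks))
        mid = 0.5 * (cal.z_lo_nm + cal.z_hi_nm)
        half = 0.5 * (cal.z_hi_nm - cal.z_lo_nm)
        u_ref = (np.clip(z_ref, cal.z_lo_nm, cal.z_hi_nm) - mid) / half
        slopes = np.array(
            [
                abs(
                    np.polynomial.polynomial.polyval(
                        u_ref, np.polynomial.polynomial.polyder(cal.coeffs[i])
                    )
                ) / half
                for i in usable
            ]
        )
        w = (np.asarray(amplitudes, dtype=float)[usable] * slopes) ** 2
        if w.sum() > 0:
            weights = w / w.sum()
    z_hat = float(np.sum(weights * picks))
    flag = FLAG_OK if np.sqrt(var) <= confidence_sd_nm else FLAG_LOW_CONFIDENCE
    return z_hat, flag, picks


@dataclass
class Track:
    """Per-frame 3D track with sampling rate and provenance metadata."""

    data: pd.DataFrame
    f_s: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)


def track_video(
    stack,
    refs: ReferenceSet,
    cal: PhaseCalibration,
    f_s: float = 30.0,
    z_window=None,
    pixel_size_nm: float = 112.0,
    n_multiply: int | None = None,
    phase_window: int = 10,
    window_halfwidth_nm: float = 1500.0,
    meta: dict | None = None,
) -> Track:
    """Track a hologram stack frame by frame.

    The z search window for frame i is centered on frame i-1's height
    (+/- ``window_halfwidth_nm``); the first frame (and any frame following
    an untrackable one) uses ``z_window``, defaulting to the full calibrated
    range.  Untrackable frames get NaN coordinates and a flag; tracking
    continues.
    """
    if z_window is None:
        z_window = (cal.z_lo_nm, cal.z_hi_nm)
    rows = []
    prev_z = None
    for i, frame in enumerate(stack):
        fix = analyze_frame(frame, refs, n_multiply=n_multiply,
                            phase_window=phase_window)
        if prev_z is not None and np.isfinite(prev_z):
            win = (prev_z - window_halfwidth_nm, prev_z + window_halfwidth_nm)
        else:
            win = z_window
        if fix.flag in ("no_bead",):
            z, zflag = np.nan, FLAG_UNTRACKABLE
        else:
            z, zflag, _ = resolve_z(
                fix.phases[cal.source_indices], cal, win,
                amplitudes=fix.amplitudes[cal.source_indices],
            )
        flag = fix.flag or zflag
        row = {
            "frame": i,
            "t_s": i / f_s,
            "x_nm": fix.x_px * pixel_size_nm,
            "y_nm": fix.y_px * pixel_size_nm,
            "z_nm": z,
            "amplitude": fix.peak_amplitude,
            "flag": flag,
        }
        for k, phi in zip(refs.periods, fix.phases):
            row[f"phi_k{k:.2f}"] = phi
        rows.append(row)
        prev_z = z if np.isfinite(z) else prev_z
    df = pd.DataFrame(rows)
    meta = dict(meta or {})
    meta.setdefault("pixel_size_nm", pixel_size_nm)
    meta.setdefault("n_periods", refs.n_periods)
    return Track(data=df, f_s=f_s, meta=meta)
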