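"""Step-size quantification for force-extension curves.

In nucleosome-unwrapping experiments the tether's released contour length
grows in discrete steps of a few tens of base pairs.  Each recorded
(force, extension) point is compared against the worm-like-chain (WLC)
extension of every trial contour length; the z-score probability that the
point belongs to that contour length is summed over all points, producing a
probability landscape over contour length whose peaks mark stable states.
Neighboring-peak spacings are collected into a step histogram and fitted
with a Gaussian mixture whose components sit at (1, 2, 3) x the fundamental
step, accounting for double and triple simultaneous steps.

The WLC is the inextensible Marko-Siggia interpolation

    F = (kT / L_p) * [ 1/4 (1 - z/L)^-2 - 1/4 + z/L ],

with persistence length L_p = 50 nm and kT = 4.11 pN nm by default (room
temperature, standard DNA values); 0.34 nm/bp converts contour length
between nm and base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks


@dataclass(frozen=True)
class WLCParams:
    """Polymer and noise parameters for the WLC z-score landscape."""

    persistence_nm: float = 50.0
    kbt_pn_nm: float = 4.11
    nm_per_bp: float = 0.34
    sigma_track_nm: float = 2.0

    def __post_init__(self):
        for name in ("persistence_nm", "kbt_pn_nm", "nm_per_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_track_nm < 0:
            raise ValueError("sigma_track_nm must be >= 0")


@dataclass
class FECurve:
    """Paired (force pN, extension nm) samples, ordered by force."""

    force_pn: np.ndarray
    extension_nm: np.ndarray

    def __post_init__(self):
        self.force_pn = np.asarray(self.force_pn, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        if self.force_pn.shape != self.extension_nm.shape:
            raise ValueError("force and extension must be paired")
        if np.any(self.force_pn <= 0):
            raise ValueError("forces must be positive")
        if np.any(~np.isfinite(self.extension_nm)):
            raise ValueError("extensions must be finite")


@dataclass
class StepAnalysis:
    """Probability landscape, detected states, and the step-size fit."""

    grid_bp: np.ndarray
    probability: np.ndarray
    peaks_bp: np.ndarray = field(default_factory=lambda: np.array([]))
    steps_bp: np.ndarray = field(default_factory=lambda: np.array([]))
    hist_bin_bp: float = 12.0
    mixture: dict = field(default_factory=dict)
    fundamental_bp: float = np.nan


def wlc_force(z_nm, contour_nm: float, p: WLCParams) -> np.ndarray:
    """Marko-Siggia force at relative extension z/L (z in (0, L))."""
    zl = np.asarray(z_nm, dtype=float) / contour_nm
    return (p.kbt_pn_nm / p.persistence_nm) * (
        0.25 / (1.0 - zl) ** 2 - 0.25 + zl
    )


def wlc_extension(contour_nm, force_pn, p: WLCParams) -> np.ndarray:
    """Extension solving the Marko-Siggia relation at the given force.

    Solved by bracketed root finding in z/L on (0, 1); monotone in force.
    Broadcasts over either argument.
    """
    L = np.atleast_1d(np.asarray(contour_nm, dtype=float))
    F = np.atleast_1d(np.asarray(force_pn, dtype=float))
    if np.any(L <= 0) or np.any(F <= 0):
        raise ValueError("contour length and force must be positive")
    c = p.kbt_pn_nm / p.persistence_nm

    def rel_ext(f: float) -> float:
        g = lambda u: c * (0.25 / (1.0 - u) ** 2 - 0.25 + u) - f
        return brentq(g, 1e-12, 1.0 - 1e-9, xtol=1e-12, rtol=1e-14)

    # the relative extension depends on force only; solve per unique force
    uniq, inv = np.unique(F, return_inverse=True)
    zl = np.array([rel_ext(f) for f in uniq])[inv].reshape(F.shape)
    out = zl * L
    return out[0] if np.isscalar(contour_nm) and np.isscalar(force_pn) else out


def wlc_compliance(contour_nm, force_pn, p: WLCParams) -> np.ndarray:
    """dz/dF from the analytic derivative of the Marko-Siggia relation."""
    z = wlc_extension(contour_nm, force_pn, p)
    L = np.asarray(contour_nm, dtype=float)
    zl = np.asarray(z) / L
    dF_dz = (p.kbt_pn_nm / p.persistence_nm) * (
        0.5 / (1.0 - zl) ** 3 + 1.0
    ) / L
    return 1.0 / dF_dz


def point_sd(force_pn, contour_nm, p: WLCParams) -> np.ndarray:
    """Expected SD of one extension sample at (F, L).

    Equipartition gives thermal variance kT * dz/dF; the tracking error adds
    in quadrature: sigma^2 = kT (dz/dF) + sigma_track^2.
    """
    var = p.kbt_pn_nm * wlc_compliance(contour_nm, force_pn, p)
    return np.sqrt(var + p.sigma_track_nm**2)


def state_probability(curve: FECurve, grid_bp, p: WLCParams) -> StepAnalysis:
    """Summed z-score probability of the curve at each trial contour length.

    For each grid contour length L the standard normal density of the
    z score (z_i - z_WLC(L, F_i)) / sigma_i is summed over all data points;
    peaks of the landscape mark stable unwrapping states.
    """
    grid_bp = np.asarray(grid_bp, dtype=float)
    if len(curve.force_pn) == 0:
        raise ValueError("empty force-extension curve")
    if len(grid_bp) > 1 and np.any(np.diff(grid_bp) > 1.0):
        import warnings

        warnings.warn("contour-length grid coarser than 1 bp may miss peaks",
                      stacklevel=2)
    F = curve.force_pn
    z = curve.extension_nm
    # the relative WLC extension depends only on F: solve once per point and
    # scale by the trial contour length (vectorized over the whole grid)
    zl = wlc_extension(1.0, F, p)
    c = p.kbt_pn_nm / p.persistence_nm
    dFdz_rel = c * (0.5 / (1.0 - zl) ** 3 + 1.0)  # = dF/dz * L
    L = grid_bp[:, np.newaxis] * p.nm_per_bp  # (n_grid, 1)
    z_th = zl[np.newaxis, :] * L
    var = p.kbt_pn_nm * L / dFdz_rel[np.newaxis, :] + p.sigma_track_nm**2
    zscore = (z[np.newaxis, :] - z_th) / np.sqrt(var)
    prob = np.sum(np.exp(-0.5 * zscore**2), axis=1) / np.sqrt(2.0 * np.pi)
    return StepAnalysis(grid_bp=grid_bp, probability=prob)


def find_steps(
    analysis: StepAnalysis,
    prominence_frac: float = 0.10,
    min_separation_bp: float = 20.0,
) -> StepAnalysis:
    """Detect landscape peaks and neighbor step sizes (in place).

    Peaks must rise by at least ``prominence_frac`` of the landscape maximum
    and be at least ``min_separation_bp`` apart.
    """
    grid = analysis.grid_bp
    dx = float(np.mean(np.diff(grid))) if len(grid) > 1 else 1.0
    idx, _ = find_peaks(
        analysis.probability,
        prominence=prominence_frac * analysis.probability.max(),
        distance=max(int(round(min_separation_bp / dx)), 1),
    )
    analysis.peaks_bp = grid[idx]
    analysis.steps_bp = (
        np.diff(analysis.peaks_bp) if len(idx) >= 2 else np.array([])
    )
    return analysis


def _mixture_model(x, delta, sigma, a1, a2, a3):
    out = np.zeros_like(x)
    for k, a in enumerate((a1, a2, a3), start=1):
        out += a * np.exp(-0.5 * ((x - k * delta) / sigma) ** 2)
    return out


def fit_step_histogram(
    steps_bp,
    bin_width_bp: float = 12.0,
    n_components: int = 3,
    delta0: float | None = None,
) -> dict:
    """Least-squares Gaussian-mixture fit of the step-size histogram.

    Component k is centered at k * delta (double / triple simultaneous
    steps), with a shared width and free amplitudes; the fitted ``delta`` is
    the fundamental step.  Returns a dict with means, width, amplitudes,
    counts per component and ``fundamental_bp``.
    """
    steps = np.asarray(steps_bp, dtype=float)
    if len(steps) < 10:
        raise ValueError("need >= 10 steps for a histogram fit")
    if n_components != 3:
        raise ValueError("the histogram model uses 3 components (1-3 x delta)")
    # histogram out to 3x the largest step so that the double/triple
    # components are constrained by (possibly empty) bins
    edges = np.arange(0.0, 3.0 * steps.max() + 2 * bin_width_bp, bin_width_bp)
    counts, edges = np.histogram(steps, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if delta0 is None:
        delta0 = centers[np.argmax(counts)]
    p0 = [delta0, bin_width_bp, counts.max(), counts.max() / 4, counts.max() / 8]
    lo = [bin_width_bp / 2, 1.0, 0.0, 0.0, 0.0]
    hi = [steps.max() + bin_width_bp, steps.max() + bin_width_bp, np.inf, np.inf, np.inf]
    popt, _ = curve_fit(
        _mixture_model, centers, counts, p0=p0, bounds=(lo, hi), maxfev=20000,
    )
    delta, sigma, *amps = popt
    amps = np.asarray(amps)
    comp_counts = amps * sigma * np.sqrt(2 * np.pi) / bin_width_bp
    return {
        "fundamental_bp": float(delta),
        "means_bp": [float(k * delta) for k in (1, 2, 3)],
        "sigma_bp": float(sigma),
        "amplitudes": amps.tolist(),
        "component_counts": comp_counts.tolist(),
        "bin_width_bp": float(bin_width_bp),
        "hist_counts": counts.tolist(),
        "hist_centers": centers.tolist(),
    }


def analyze_curve(
    curve: FECurve,
    substrate_bp: float,
    p: WLCParams,
    grid_step_bp: float = 1.0,
    prominence_frac: float = 0.10,
    min_separation_bp: float = 20.0,
) -> StepAnalysis:
    """Landscape + peak detection over 0..substrate contour length."""
    grid = np.arange(grid_step_bp, substrate_bp + grid_step_bp, grid_step_bp)
    analysis = state_probability(curve, grid, p)
    return find_steps(analysis, prominence_frac, min_separation_bp)


def synth_fe_curve(
    substrate_bp: float,
    step_bp: float,
    step_forces_pn,
    p: WLCParams,
    f_min_pn: float = 0.5,
    f_max_pn: float = 25.0,
    n_points: int = 400,
    noise_scale: float = 1.0,
    seed: int | None = None,
):
    """Synthetic piecewise-WLC force-extension curve with discrete steps.

    The tether starts with the substrate contour minus one step per pending
    unwrapping event and gains ``step_bp`` of contour at each force in
    ``step_forces_pn`` as the ramp passes it.  Gaussian extension noise of
    SD ``noise_scale * point_sd`` is added.  Returns (curve, truth) where
    truth lists the contour length of every state in bp.
    """
    step_forces = np.sort(np.asarray(step_forces_pn, dtype=float))
    n_steps = len(step_forces)
    if n_steps * step_bp >= substrate_bp:
        raise ValueError("total stepped contour exceeds the substrate length")
    if np.any(step_forces < f_min_pn) or np.any(step_forces > f_max_pn):
        raise ValueError("step forces must lie inside the force ramp")
    rng = np.random.default_rng(seed)
    F = np.linspace(f_min_pn, f_max_pn, n_points)
    L0_bp = substrate_bp - n_steps * step_bp
    L_bp = L0_bp + step_bp * (F[:, None] > step_forces[None, :]).sum(axis=1)
    L_nm = L_bp * p.nm_per_bp
    z = np.array([wlc_extension(float(l), float(f), p) for l, f in zip(L_nm, F)])
    if noise_scale > 0:
        sd = np.array([point_sd(float(f), float(l), p) for l, f in zip(L_nm, F)])
        z = z + rng.normal(0.0, 1.0, len(z)) * sd * noise_scale
    truth = np.unique(L_bp)
    return FECurve(force_pn=F, extension_nm=z), truth
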