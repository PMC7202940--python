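"""Lorenz-Mie hologram simulator for spherical microbeads.

Renders the in-line holographic diffraction pattern of a colloidal bead held
above the focal plane of a wide-field microscope, as used in magnetic
tweezers: the recorded intensity is the interference between the (plane)
incident field and the field scattered off the sphere,

    I(rho) = beta * [1 + f_gamma(r) * (2 alpha Re{f_s e^{-i k z_p}}
                                       + alpha^2 |f_s|^2)],

with ``f_s`` the Mie scattering amplitude evaluated at the pixel, ``alpha``
an illumination scale, ``beta`` the background grey level, and ``f_gamma`` a
raised-cosine (Hamming-type) envelope of width ``gamma`` pixels that models
the finite spatial coherence of LED illumination.  The field is treated as
scalar (polarization dropped): the trackers built on top of this model only
exploit the circular symmetry of the rings, and the envelope already absorbs
the main deviation of real LED holograms from exact Mie theory.  The
scattered wave uses the far-field outgoing form e^{ikR}/(-ikR) with R the 3D
bead-to-pixel distance; for beads defocused by >= 2 um, kR > 40 and the
near-field Hankel corrections are negligible at the grey-level resolution of
an 8-bit camera.

Coordinates: x right, y down, origin at the ROI center (pixel index
``s // 2``), pixel centers at integer coordinates; z in nm above the focal
plane, increasing away from the objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.special import spherical_jn, spherical_yn

logger = logging.getLogger(__name__)

#: z range (nm above focus) over which the far-field scalar model is trusted.
VALID_Z_RANGE_NM = (2_000.0, 20_000.0)


@dataclass(frozen=True)
class OpticalModel:
    """Bead / medium / illumination parameters of the forward model.

    Parameters
    ----------
    bead_radius_um : bead radius a in micrometers.
    bead_index : refractive index n_p of the bead.
    medium_index : refractive index n_m of the medium.
    wavelength_nm : vacuum wavelength of the illumination.
    alpha : illumination scale of the scattered field, ~1.
    beta : background intensity in grayscale units.
    gamma_px : width of the coherence envelope, in pixels.
    pixel_size_nm : camera pixel size in the sample plane.
    """

    bead_radius_um: float = 0.5
    bead_index: float = 1.9
    medium_index: float = 1.33
    wavelength_nm: float = 645.0
    alpha: float = 1.0
    beta: float = 54.0
    gamma_px: float = 45.0
    pixel_size_nm: float = 112.0

    def __post_init__(self) -> None:
        if self.bead_radius_um <= 0:
            raise ValueError("bead radius must be positive")
        if not (self.bead_index > self.medium_index >= 1.0):
            raise ValueError("need n_p > n_m >= 1")
        if self.wavelength_nm <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("wavelength and pixel size must be positive")
        if self.alpha < 0 or self.beta <= 0:
            raise ValueError("alpha >= 0 and beta > 0 required")
        if self.gamma_px <= 0:
            raise ValueError("coherence width gamma must be positive")

    @property
    def wavenumber(self) -> float:
        """k = 2 pi n_m / lambda, in 1/nm."""
        return 2.0 * np.pi * self.medium_index / self.wavelength_nm

    @property
    def size_parameter(self) -> float:
        """Mie size parameter x = k a."""
        return self.wavenumber * self.bead_radius_um * 1e3

    @property
    def relative_index(self) -> float:
        return self.bead_index / self.medium_index


@dataclass(frozen=True)
class BeadPose:
    """3D bead position: x, y lateral offsets from the ROI center and z the
    height above the focal plane, all in nm (z > 0 = defocused)."""

    x_nm: float = 0.0
    y_nm: float = 0.0
    z_nm: float = 12_000.0


@dataclass
class Hologram:
    """A rendered (or recorded) s x s diffraction pattern."""

    image: np.ndarray
    pose: BeadPose | None = None
    model: OpticalModel | None = None

    @property
    def roi_size(self) -> int:
        return self.image.shape[0]


@dataclass
class Trajectory:
    """Uniformly sampled bead trajectory at sampling rate ``f_s`` Hz."""

    poses: list[BeadPose]
    f_s: float = 30.0

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.poses)) / self.f_s

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(len(self.poses)),
                "t_s": self.times,
                "x_nm": [p.x_nm for p in self.poses],
                "y_nm": [p.y_nm for p in self.poses],
                "z_nm": [p.z_nm for p in self.poses],
            }
        )

    @classmethod
    def from_frame(cls, df, f_s: float | None = None) -> "Trajectory":
        if f_s is None:
            dt = np.diff(np.asarray(df["t_s"], dtype=float))
            f_s = 1.0 / float(np.mean(dt)) if len(dt) else 30.0
        poses = [
            BeadPose(float(r.x_nm), float(r.y_nm), float(r.z_nm))
            for r in df.itertuples()
        ]
        return cls(poses, f_s=f_s)


# ---------------------------------------------------------------------------
# Mie partial-wave series
# ---------------------------------------------------------------------------

def mie_n_terms(x: float) -> int:
    """Series truncation: Wiscombe-style N = x + 4 x^(1/3) + 2, rounded up."""
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(x: float, m: float, n_max: int | None = None):
    """Mie partial-wave coefficients a_n, b_n, n = 1..N.

    Uses the logarithmic-derivative formulation: D_n(mx) by downward
    recurrence (started well above N for stability), Riccati-Bessel
    functions psi, chi of the exterior argument from scipy's spherical
    Bessel routines.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if n_max is None:
        n_max = mie_n_terms(x)
    mx = m * x
    n_start = max(n_max, int(np.ceil(abs(mx)))) + 16
    d = np.zeros(n_start + 1, dtype=complex)
    for n in range(n_start, 0, -1):  # downward recurrence for D_n(mx)
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    n = np.arange(1, n_max + 1)
    psi = x * spherical_jn(n, x)
    chi = -x * spherical_yn(n, x)
    psi0 = np.sin(x)
    chi0 = np.cos(x)
    xi = psi - 1j * chi
    xi_prev = np.concatenate(([psi0 - 1j * chi0], xi[:-1]))
    psi_prev = np.concatenate(([psi0], psi[:-1]))
    dn = d[1 : n_max + 1]
    fa = dn / m + n / x
    fb = dn * m + n / x
    a = (fa * psi - psi_prev) / (fa * xi - xi_prev)
    b = (fb * psi - psi_prev) / (fb * xi - xi_prev)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ArithmeticError(
            f"Mie series did not converge: non-finite coefficients at x={x}, m={m}"
        )
    return a, b


def _pi_tau(mu: np.ndarray, n_max: int):
    """Angular functions pi_n(mu), tau_n(mu) for n = 1..N (vectorized)."""
    mu = np.asarray(mu, dtype=float)
    pi = np.zeros((n_max + 1,) + mu.shape)
    tau = np.zeros_like(pi)
    pi[1] = 1.0
    tau[1] = mu
    for n in range(2, n_max + 1):
        pi[n] = ((2 * n - 1) * mu * pi[n - 1] - n * pi[n - 2]) / (n - 1)
        tau[n] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau[1:]


def scattering_function(model: OpticalModel, cos_theta: np.ndarray) -> np.ndarray:
    """Scalar angular scattering amplitude S(theta) = (S1 + S2) / 2.

    S1, S2 are the standard Mie amplitude-matrix elements; their mean keeps
    the circular symmetry of the rendered hologram for unpolarized detection.
    """
    x = model.size_parameter
    m = model.relative_index
    a, b = mie_coefficients(x, m)
    n = np.arange(1, len(a) + 1)
    w = (2 * n + 1) / (n * (n + 1))
    pi_n, tau_n = _pi_tau(np.atleast_1d(cos_theta), len(a))
    s1 = np.tensordot(w * a, pi_n, axes=(0, 0)) + np.tensordot(w * b, tau_n, axes=(0, 0))
    s2 = np.tensordot(w * a, tau_n, axes=(0, 0)) + np.tensordot(w * b, pi_n, axes=(0, 0))
    out = 0.5 * (s1 + s2)
    if np.isscalar(cos_theta) or np.ndim(cos_theta) == 0:
        return out[0]
    return out


def scattering_amplitude(model: OpticalModel, displacement_nm) -> complex | np.ndarray:
    """Scattered field amplitude f_s at a displacement from the bead center.

    ``displacement_nm`` is (dx, dy, dz) with dz the axial distance from the
    bead down to the observation plane (positive when the plane is on the
    transmission side).  The far-field form e^{ikR} / (-ikR) * S(theta) is
    used; the evaluation point must lie outside the sphere.
    """
    d = np.asarray(displacement_nm, dtype=float)
    scalar = d.ndim == 1
    d = np.atleast_2d(d)
    r = np.linalg.norm(d, axis=-1)
    a_nm = model.bead_radius_um * 1e3
    if np.any(r <= a_nm):
        raise ValueError("field evaluated inside the bead (|displacement| <= a)")
    cos_theta = d[..., 2] / r
    k = model.wavenumber
    amp = scattering_function(model, cos_theta) * np.exp(1j * k * r) / (-1j * k * r)
    return amp[0] if scalar else amp


# ---------------------------------------------------------------------------
# Hologram rendering
# ---------------------------------------------------------------------------

def coherence_envelope(r_px: np.ndarray, gamma_px: float) -> np.ndarray:
    """Raised-cosine envelope f_gamma(r) = (cos(pi r / gamma) + 1) / 2 for
    r < gamma, 0 beyond; r in pixels from the bead center."""
    r_px = np.asarray(r_px, dtype=float)
    out = 0.5 * (np.cos(np.pi * r_px / gamma_px) + 1.0)
    return np.where(r_px < gamma_px, out, 0.0)


def quantize_image(image: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to the 8-bit range."""
    q = np.floor(np.abs(image) + 0.5) * np.sign(image)
    return np.clip(q, 0, 255).astype(np.uint8)


def _radial_signal(model: OpticalModel, z_nm: float, rho_max_nm: float,
                   spacing_px: float = 0.25, normalize: str = "onaxis"):
    """Scattering contribution g(rho) on a 1D lateral-radius grid.

    g(rho) = f_gamma(rho) * (2 alpha Re{f_s e^{-ikz}} + alpha^2 |f_s|^2);
    the hologram is then beta * (1 + g) interpolated onto the pixel grid.

    With ``normalize='onaxis'`` (default) the scattering function is scaled
    to unit magnitude on the optical axis at the bead's height, so that
    alpha is the fringe contrast of the central interference term.  This is
    the convention under which alpha ~ 1 with beta ~ 54 grayscale produces
    the nearly full-range 8-bit diffraction patterns recorded for 1 um
    paramagnetic beads; the raw far-field amplitude (``normalize='raw'``)
    gives |f_s| = |S(0)| / kz ~ 0.2 at 12 um defocus instead.
    """
    px = model.pixel_size_nm
    n_pts = int(np.ceil(rho_max_nm / (spacing_px * px))) + 3
    rho = np.linspace(0.0, rho_max_nm + 2 * spacing_px * px, n_pts)
    r3 = np.sqrt(rho**2 + z_nm**2)
    cos_theta = z_nm / r3
    k = model.wavenumber
    fs = scattering_function(model, cos_theta) * np.exp(1j * k * r3) / (-1j * k * r3)
    fs = fs * np.exp(-1j * k * z_nm)
    if normalize == "onaxis":
        fs = fs / (np.abs(scattering_function(model, 1.0)) / (k * z_nm))
    elif normalize != "raw":
        raise ValueError("normalize must be 'onaxis' or 'raw'")
    g = 2.0 * model.alpha * fs.real + model.alpha**2 * np.abs(fs) ** 2
    g *= coherence_envelope(rho / px, model.gamma_px)
    return rho, g


def render_hologram(
    model: OpticalModel,
    pose: BeadPose,
    roi_size: int = 150,
    quantize: bool = True,
    envelope: str = "scattering",
    normalize: str = "onaxis",
    radial_spacing_px: float = 0.25,
) -> Hologram:
    """Render the LMST hologram of a bead at ``pose`` in an s x s ROI.

    ``envelope='scattering'`` (default) applies the coherence envelope to the
    interference and scattering terms only, so the background stays at beta
    across the whole ROI as in recorded images; ``envelope='full'`` applies
    it to the entire bracket (the literal parenthesization of the printed
    model, in which the background itself decays to zero at the ROI edge).
    """
    s = int(roi_size)
    if s < 32:
        raise ValueError("roi_size must be >= 32")
    if model.gamma_px <= 0:
        raise ValueError("gamma must be positive")
    if envelope not in ("scattering", "full"):
        raise ValueError("envelope must be 'scattering' or 'full'")
    z = pose.z_nm
    if not (VALID_Z_RANGE_NM[0] <= z <= VALID_Z_RANGE_NM[1]):
        logger.warning(
            "pose z = %.0f nm outside validated range %s; rendering anyway",
            z, VALID_Z_RANGE_NM,
        )
    px = model.pixel_size_nm
    c = s // 2
    xs = (np.arange(s) - c) * px - pose.x_nm
    ys = (np.arange(s) - c) * px - pose.y_nm
    rho = np.hypot(xs[np.newaxis, :], ys[:, np.newaxis])
    rho_grid, g_grid = _radial_signal(
        model, z, float(rho.max()), radial_spacing_px, normalize=normalize,
    )
    g = CubicSpline(rho_grid, g_grid)(rho)
    if envelope == "scattering":
        image = model.beta * (1.0 + g)
    else:
        env = coherence_envelope(rho / px, model.gamma_px)
        # literal reading: envelope multiplies background and scattering alike
        image = model.beta * (env + g)
    image = quantize_image(image) if quantize else image
    return Hologram(image=image, pose=pose, model=model)


def render_video(
    model: OpticalModel,
    traj: Trajectory,
    roi_size: int = 150,
    quantize: bool = True,
    **kwargs,
) -> np.ndarray:
    """Render one frame per trajectory sample; returns an (n, s, s) stack."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    frames = [
        render_hologram(model, pose, roi_size, quantize=quantize, **kwargs).image
        for pose in traj.poses
    ]
    return np.stack(frames)


# ---------------------------------------------------------------------------
# Forward-model fitting
# ---------------------------------------------------------------------------

#: order of the full parameter vector used by fit_lmst
FIT_PARAM_NAMES = (
    "x_nm", "y_nm", "z_nm", "bead_radius_um", "bead_index",
    "medium_index", "alpha", "beta", "gamma_px",
)

#: parameters held fixed by default (radius and medium index are known)
DEFAULT_FIXED = ("bead_radius_um", "medium_index")


@dataclass
class LMSTFit:
    """Result of a nonlinear least-squares fit of the hologram model."""

    model: OpticalModel
    pose: BeadPose
    stderr: dict = field(default_factory=dict)
    residual: np.ndarray | None = None
    success: bool = True
    message: str = ""
    cost: float = 0.0

    def params(self) -> dict:
        return {
            "x_nm": self.pose.x_nm,
            "y_nm": self.pose.y_nm,
            "z_nm": self.pose.z_nm,
            "bead_radius_um": self.model.bead_radius_um,
            "bead_index": self.model.bead_index,
            "medium_index": self.model.medium_index,
            "alpha": self.model.alpha,
            "beta": self.model.beta,
            "gamma_px": self.model.gamma_px,
        }


def _unpack(theta: dict) -> tuple[OpticalModel, BeadPose]:
    pose = BeadPose(theta["x_nm"], theta["y_nm"], theta["z_nm"])
    model = OpticalModel(
        bead_radius_um=theta["bead_radius_um"],
        bead_index=theta["bead_index"],
        medium_index=theta["medium_index"],
        wavelength_nm=theta["wavelength_nm"],
        alpha=theta["alpha"],
        beta=theta["beta"],
        gamma_px=theta["gamma_px"],
        pixel_size_nm=theta["pixel_size_nm"],
    )
    return model, pose


def fit_lmst(
    image: np.ndarray | Hologram,
    init_model: OpticalModel,
    init_pose: BeadPose,
    fixed: tuple[str, ...] = DEFAULT_FIXED,
    max_nfev: int = 200,
    z_scan: bool = True,
) -> LMSTFit:
    """Fit the forward model to a hologram by nonlinear least squares.

    Free parameters default to (x, y, z, n_p, alpha, beta, gamma); the bead
    radius and medium index are fixed, as is standard when they are known
    from the bead supplier and buffer.  The cost surface is oscillatory in z
    with minima one interference fringe (lambda / 2 n_m) apart, so unless
    ``z_scan`` is disabled the initial height is first refined by a coarse
    scan over +/- 10% (or at least +/- 3 fringes) before the least-squares
    polish.  Returns best-fit parameters, asymptotic standard errors and the
    residual image; non-convergence is reported through
    ``success``/``message``, not an exception.
    """
    data = image.image if isinstance(image, Hologram) else image
    data = np.asarray(data, dtype=float)
    s = data.shape[0]
    base = {
        **{k: getattr(init_pose, k) for k in ("x_nm", "y_nm", "z_nm")},
        "bead_radius_um": init_model.bead_radius_um,
        "bead_index": init_model.bead_index,
        "medium_index": init_model.medium_index,
        "alpha": init_model.alpha,
        "beta": init_model.beta,
        "gamma_px": init_model.gamma_px,
        "wavelength_nm": init_model.wavelength_nm,
        "pixel_size_nm": init_model.pixel_size_nm,
    }
    free = [p for p in FIT_PARAM_NAMES if p not in fixed]
    scales = {
        "x_nm": 100.0, "y_nm": 100.0, "z_nm": 1000.0, "bead_radius_um": 0.1,
        "bead_index": 0.1, "medium_index": 0.05, "alpha": 0.1, "beta": 10.0,
        "gamma_px": 10.0,
    }

    def polish(start: dict, free_now: list[str]):
        def resid(v):
            theta = dict(start)
            theta.update(dict(zip(free_now, v)))
            try:
                model, pose = _unpack(theta)
                rendered = render_hologram(model, pose, s, quantize=False).image
            except (ValueError, ArithmeticError):
                return np.full(data.size, 1e6)
            return (rendered - data).ravel()

        x0 = np.array([start[p] for p in free_now], dtype=float)
        return least_squares(
            resid, x0, x_scale=[scales[p] for p in free_now],
            max_nfev=max_nfev,
            method="lm" if len(free_now) <= data.size else "trf",
        )

    # The cost surface is oscillatory in z: local minima sit one
    # interference fringe (lambda / 2 n_m) apart, each with its own
    # compensating refractive-index/contrast values, so a single local
    # polish settles in whichever fringe the start fell.  Profile the cost
    # over fringe-spaced heights (z held fixed, everything else refit) and
    # start the final free polish from the best one.
    if z_scan and "z_nm" in free and len(free) > 1:
        fringe = init_model.wavelength_nm / (2.0 * init_model.medium_index)
        span = max(0.1 * base["z_nm"], 3.0 * fringe)
        zs = base["z_nm"] + np.arange(-span, span + fringe / 2, fringe / 2)
        zs = zs[zs > VALID_Z_RANGE_NM[0] / 2]
        free_profile = [p for p in free if p != "z_nm"]
        rel_tol = 1e-10 * data.size
        best = None
        for z_try in zs:
            res_p = polish(dict(base, z_nm=z_try), free_profile)
            if best is None or res_p.cost < best[0]:
                start = dict(base, z_nm=z_try,
                             **dict(zip(free_profile, res_p.x)))
                best = (res_p.cost, start)
            if best[0] <= rel_tol:
                break
        base = best[1]

    res = polish(base, free)
    theta = dict(base, **dict(zip(free, res.x)))
    model, pose = _unpack(theta)
    resid = res.fun.reshape(data.shape)
    dof = max(data.size - len(free), 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        stderr = dict(zip(free, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    except np.linalg.LinAlgError:
        stderr = {p: np.nan for p in free}
    success = bool(res.status > 0)
    if not success:
        logger.warning("LMST fit did not converge: %s", res.message)
    return LMSTFit(
        model=model, pose=pose, stderr=stderr, residual=-resid,
        success=success, message=res.message, cost=float(res.cost),
    )
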