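# Methods

## Forward model: scalar Lorenz–Mie holograms

A bead of radius *a* and index *n_p* in a medium of index *n_m*, held a
height *z_p* above the focal plane and illuminated by a collimated beam of
vacuum wavelength λ, produces in the focal plane the interference pattern

    I(ρ) = β [ 1 + f_γ(r) ( 2α Re{ f_s(ρ − ρ_p) e^{−i k z_p} } + α² |f_s|² ) ]

with k = 2π n_m / λ. The scattered amplitude is evaluated with the standard
Mie partial-wave series: coefficients a_n, b_n from the logarithmic-
derivative downward recurrence, truncated at N = ⌈x + 4x^{1/3} + 2⌉ for
size parameter x = k a (x ≈ 6.48 for the standard 1 μm bead), and the
outgoing far-field form e^{ikR}/(−ikR) · S(θ) with R the 3D bead-to-pixel
distance and S = (S₁+S₂)/2.

Deliberate simplifications, and why they are safe here:

- **Scalar field.** Polarization is dropped (S = (S₁+S₂)/2 keeps circular
  symmetry). The trackers only exploit the circular symmetry of the rings,
  and real LED holograms of composite paramagnetic beads deviate from
  vector Mie theory by more than this approximation does.
- **Far-field radial dependence.** At z ≥ 4 μm, kR > 80, so the spherical
  Hankel functions are indistinguishable from their asymptotic form at
  8-bit grey-level resolution.
- **On-axis normalization.** The scattering function is rescaled to unit
  magnitude on the optical axis at the bead height, so that α is the
  fringe contrast of the central interference term. This is the convention
  under which the canonical parameter set (α = 1, β = 54) produces
  realistic, nearly full-range 8-bit diffraction patterns; the raw
  far-field amplitude (|f_s| = |S(0)|/kz ≈ 0.2 at 12 μm) is available via
  `normalize="raw"`.
- **Coherence envelope on the scattering terms only.** f_γ(r) =
  (cos(πr/γ)+1)/2 for r < γ (else 0), centered on the *bead*, multiplies
  the interference and |f_s|² terms but not the unit background: recorded
  images show a flat background out to the ROI corners. The literal
  reading, with the envelope over the whole bracket, is available via
  `envelope="full"`. The envelope models the finite spatial coherence of
  LED illumination; γ = 45 px for the standard bead.

Rendering evaluates the radial signal on a 1D grid (0.25 px spacing) and
maps it onto pixels with a cubic spline; the interpolation error is below
0.1 grey levels. Coordinates: x right, y down, origin at the ROI center
(pixel index s//2), z in nm above focus. Quantization rounds half away
from zero and clips to [0, 255]; fitting always uses float images.

**Model fitting** (`fit_lmst`) is nonlinear least squares over
(x, y, z, n_p, α, β, γ) with *a* and *n_m* fixed. The cost surface is
oscillatory in z with local minima one interference fringe (λ/2n_m ≈
242 nm) apart, each with compensating (n_p, α, γ); the fit therefore
profiles the cost over fringe-spaced heights (z fixed, all else refit)
across ±max(10% z, 3 fringes) before the final free polish. Asymptotic
standard errors come from the Gauss–Newton covariance.

## The phasor tracker

Per frame, the image is cross-correlated (cyclically, via FFTs) with
cached complex reference images `I_n(r) = f_win(r) e^{2πi r/k_n}`, one per
radial period k_n, each band-passed by a Gaussian annulus centered at
1/k_n cycles/px with SD `rel_bandwidth / k_n` (default 0.2/k_n, keeping
neighboring log-spaced periods largely separated). Periods below 7 px do
not produce a distinct correlation peak at this wavelength and pixel size.

- ***xy*:** the amplitude maps of the five periods with the most distinct
  peaks (max/median ratio) are multiplied; the bead position is the
  centroid of the product above half its maximum, inside a ±16 px
  neighborhood of the argmax. The peak-selection step matters because the
  correlation amplitude of each period varies strongly with defocus — at
  12 μm the 7–9 px periods carry almost no signal and their maps are
  noise; the centroid (rather than a 3-point parabola through the
  many-pixel-wide peak top) keeps the estimator noise-averaging and
  sub-pixel accurate (< 0.04 px bias on noiseless images).
- ***φ_n*:** the amplitude-weighted circular mean of the complex
  correlation over a 10×10 px window at the rounded peak. Circular
  averaging makes wrap-around at ±π harmless.
- ***z*:** see calibration below.

## Phase–height calibration and 2π disambiguation

On a focus ramp with known heights, each period's phase is unwrapped
(2π jumps removed; the fitted curve, not the jittery raw sequence, is
required to be monotonic — the order is reduced stepwise if a high-order
fit wiggles) and fitted with a polynomial of order p (default 5, as
appropriate for a 10 μm range starting 5 μm above focus; order 15 is used
by the full-protocol benchmarks; beyond ~10 the tracking accuracy stops
improving). Residual SDs are converted to nm through the local slope.
Far from focus the phase is nearly linear in z with slope ∝ k_n^e; the
exponent is measured from the fitted slopes rather than assumed and comes
out ≈ −1.2 with these optics (finer references are more height-sensitive;
the stationary-phase prediction for an ideal chirp is −2, softened here by
the bandpass and amplitude weighting). The per-period linear asymptotes
extrapolate to a common intersection, which anchors the focus estimate
(closed-form least-squares intersection).

At track time a measured phase determines height only modulo 2π. For each
period, all candidate heights inside a search window are enumerated
through the monotone inverse interpolant; every candidate anchors a
combination built from the nearest candidate of each other period, and
the combination with the smallest sample variance wins (ties toward the
lowest mean). Periods with no candidate in the window (no signal at this
defocus) drop out; a frame is untrackable only when fewer than two
periods remain. The winning combination is averaged with inverse-variance
weights (amplitude × local slope)², since a period's phase noise scales
inversely with its correlation amplitude. The per-frame window is
centered on the previous frame's height (±1.5 μm, covering any plausible
inter-frame motion at 30 Hz); the first frame uses the full calibrated
range.

## Synthetic-data protocols

The generator reproduces the canonical validation conditions:

- **Optics:** a = 0.5 μm, n_p = 1.9, n_m = 1.33, λ = 645 nm, α = 1,
  β = 54, γ = 45 px, 112 nm pixels — a realistic 1 μm paramagnetic bead.
- **Standard simulation:** 3600 frames (150×150 px, 8-bit) of a bead with
  per-frame independent Gaussian displacements dx, dy = 0 ± 5 nm,
  dz = 12,000 ± 5 nm, equivalent to 120 s at 30 Hz. The test-suite runs a
  600-frame version with correspondingly wider tolerances.
- **Calibration ramp:** a linear focus scan, 4 → 16 μm in 241 frames,
  fitted over 5–15 μm.
- **Aberrations:** shot noise (per-pixel variance ∝ intensity, severity =
  variance in grey² at the image mean — the scaling under which tracking
  error grows linearly with severity, as for real cameras; a Gaussian
  fixed-SD reading of "noise amplitude" would grow quadratically);
  interlacing (alternate rows × (1 + s/100)); a linear y light gradient
  reaching (s/100)·(255 − mean) at the far edge; astigmatism (y resampled
  to aspect ratio 1 + s/100, edge-padded); and out-of-ROI drift (mean x
  offset of s% of the ROI, applied to the trajectory).

What the generator does **not** emulate: speckle and background structure
of real illumination, bead-to-bead heterogeneity (composite paramagnetic
beads are poorly described by a single refractive index), camera
nonlinearity, and mechanical drift/vibration of a physical instrument
(drift is injected analytically where needed). Passing benchmarks on this
synthetic data therefore validates the algorithmic chain — not the full
instrument — and absolute accuracies on real hardware are expected to be
somewhat worse and drift-limited at low frequencies.

## Accuracy metric

Tracking accuracy is the high-frequency plateau σ²/f_s of the position (or
tracking-error) PSD, fitted as a horizontal line above f_min (default
5 Hz; 2 Hz is sometimes preferred when drift is mild). The density is the
**two-sided** one reported at positive frequencies: white position noise
of SD σ has plateau σ²/f_s, and the implied SD is √(plateau · f_s) — the
convention that makes 0.2 nm²/Hz at 30 Hz mean 2.4 nm (a textbook
one-sided density would carry a factor 2). Parseval then reads
2·Σ P·Δf = var (Nyquist bin counted once), enforced to 1% in the tests.
Common-mode drift across beads is removed by subtracting the across-bead
mean trace after a zero-phase 4th-order Butterworth low-pass at 1 Hz
(forward–backward, so the subtracted mode has no phase lag).

## LUT baseline

The comparison tracker sums the central five rows/columns, correlates each
1D trace with its mirror (bead center = half the lag of the correlation
maximum, 3-point quadratic refinement), computes a radial profile in
1-px annuli (nearest-bin assignment of pixel-center distances, empty
annuli interpolated), and interpolates z from the quadratic vertex of the
RMS difference against 64 pre-computed profiles. Querying an exact
calibration profile returns its node height exactly; grid-edge minima are
clamped and flagged. Under shot noise the LUT develops a systematic z
bias that the phasor tracker does not, and a few percent of frames show
large xy-driven outliers — benchmark tables therefore report median ± IQR.

## Step-size analysis

Force–extension curves are compared against the inextensible Marko–Siggia
worm-like chain, F = (kT/L_p)[¼(1−z/L)⁻² − ¼ + z/L], solved for z by
bracketed root finding (forward/inverse consistent to 1e-8). Defaults:
L_p = 50 nm, kT = 4.11 pN·nm, 0.34 nm/bp — standard double-stranded DNA
values at room temperature; the tracking error σ_track (default 2 nm)
adds in quadrature to the equipartition SD √(kT·dz/dF). For every trial
contour length L on a 1 bp grid, the standard normal density of each
point's z-score is summed; landscape peaks (prominence ≥ 10% of the
maximum, ≥ 20 bp apart) mark stable states, and neighbor spacings are the
step sizes. The step histogram (12 bp bins, extended to 3× the largest
step so the higher components are constrained by empty bins) is fitted by
least squares with a three-Gaussian mixture whose means are held at
(1, 2, 3)·Δ — double and triple simultaneous steps — with shared width
and free amplitudes; Δ is the fundamental step. An extensible WLC and an
EM fit on raw steps were considered and left as future options; the
histogram least-squares matches how such distributions are usually
reported.

## Numerical and design notes

- Ties at correlation argmaxima break toward the smallest row-major index;
  all benchmark randomness flows from a single `numpy` SeedSequence, so
  identical seeds give identical tables bit for bit.
- Cross correlations are cyclic (no zero-padding); a bead near the ROI
  edge wraps around, which is exactly the failure mode probed by the
  out-of-ROI benchmark (tracking is unaffected up to ~30% mean shift;
  x and z are lost beyond ~45%, y — orthogonal to the shift — survives).
- The calibration store (`PhaseCalibration`) serializes to JSON with
  polynomial coefficients in a conditioned variable u = (z − mid)/half;
  inverse interpolants are rebuilt on load from a 4096-point grid (forward
  ∘ inverse identity within 1 nm).
- Degenerate inputs are flagged, not fatal: flat line traces, all-zero
  correlation maps, untrackable frames (NaN coordinates + flag, tracking
  continues), LUT minima at the grid edge.
- The lateral accuracy of the phasor tracker on noiseless quantized images
  (~0.06 nm²/Hz) is an order of magnitude better than the ~0.5 nm²/Hz
  that 3-point polynomial peak interpolation is limited to by pixel
  locking; as a consequence lateral accuracy here degrades *relative to
  its own baseline* under shot noise rather than appearing
  noise-independent, while staying at or below the absolute accuracy of
  the interpolation-limited estimator at every severity.

## Known limitations

- The γ = 45 px coherence envelope starves the shortest reference period
  (k = 7 px) of signal more than ~9 μm above focus: its calibration
  residual is ~24 nm over the 10 μm range (the longer periods give
  2–4 nm) and its phase contributes little at 12 μm defocus. Real optics
  with longer coherence keep k = 7 useful over the full range.
- z below ~2 μm (near focus) is outside the validated simulator range;
  the calibration deliberately starts 5 μm above focus.
- Multi-bead fields are handled as a loop over ROIs; there is no
  parallel/streaming machinery.
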