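# phasortrack

Nanometric 3D tracking of microbeads in holographic wide-field images,
built around an FFT-phasor algorithm.

Single-molecule force spectroscopy with magnetic tweezers (and TPM, AFS)
reads out the extension of a tethered biomolecule from the 3D position of a
micron-sized bead. Away from focus the bead appears as a concentric-ring
diffraction pattern; its center gives *x, y* and the expansion of the rings
encodes the height *z*. Fitting every frame to Lorenz–Mie scattering theory
is accurate but takes seconds per bead; this package implements the fast
alternative used for real-time multiplexed tracking, together with
everything needed to validate it on synthetic data:

- **`optics`** — a Lorenz–Mie hologram simulator:
  `I(ρ) = β [1 + f_γ(r)(2α Re{f_s e^{−ikz_p}} + α²|f_s|²)]`, with `f_s` the
  Mie scattering amplitude (partial-wave series with Wiscombe truncation),
  `f_γ` a raised-cosine coherence envelope of width γ pixels, and a
  nonlinear least-squares fitter for the forward model.
- **`phasor` / `zcal`** — the 3D phasor tracker: band-passed FFT cross
  correlation with computer-generated complex reference images
  `I_n(r) = f_win(r) e^{2πi r/k_n}` of single radial periods `k_n`
  (7–16 px). The product of the correlation amplitude maps peaks at the
  bead's *xy* position; the correlation phases `φ_n` grow monotonically
  with height and are converted to *z* through per-period polynomial
  calibrations, with the 2π ambiguity resolved by combining periods
  (`φ_n ∝ c k_n^e z` far from focus, e ≈ −1.2 for these optics).
- **`lut`** — the traditional look-up-table baseline (mirror-correlation
  *xy*, radial-profile RMS *z*).
- **`aberrations`** — shot noise, interlacing, light gradients, astigmatism
  and out-of-ROI drift at percentage severities, plus a robustness
  benchmark over the grid.
- **`metrics`** — tracking accuracy as the PSD plateau σ²/f_s (nm²/Hz),
  the σ = √(plateau·f_s) conversion, and common-mode drift removal.
- **`stepping`** — worm-like-chain z-score probability landscapes for
  quantifying discrete DNA-unwrapping steps in force–extension curves.

The two trackers are scikit-learn-style estimators (`PhasorTracker`,
`LUTTracker`): `fit(stack, z_true)` calibrates on a focus ramp with known
heights, `predict(stack)` returns a per-frame coordinate table in nm.

## Worked example

```python
import numpy as np
from phasortrack import PhasorTracker, protocols, render_video
from phasortrack.metrics import psd, plateau, plateau_to_sd

# calibrate on a simulated piezo focus ramp (4 -> 16 um above focus)
stack, z_true = protocols.render_calibration_stack(n_frames=241)
tracker = PhasorTracker(n_periods=15, poly_order=15).fit(stack, z_true)
print(np.round(tracker.sigma_res_nm_[-5:], 1))

# track a bead diffusing around 12 um defocus (600 frames at 30 Hz)
traj = protocols.standard_trajectory(600, seed=11)
video = render_video(protocols.standard_model(), traj, 150)
track = tracker.predict(video)

err = track["z_nm"].to_numpy() - traj.to_frame()["z_nm"].to_numpy()
p = plateau(psd(err, 30.0), f_min=5.0)
print(f"z plateau {p:.3f} nm^2/Hz -> SD {plateau_to_sd(p, 30.0):.2f} nm")
```

printed (seed 11):

```
[ 7.9  6.3  5.2  4.5  4.2]
z plateau 0.038 nm^2/Hz -> SD 1.06 nm
```

The first line is the calibration residual SD (nm) of the five longest
reference periods — the phase→height polynomials track the ramp to a few
nm over a 10 μm range. The second line is the tracking accuracy on the
standard random-motion simulation: a z error PSD plateau of ~0.04 nm²/Hz,
i.e. ~1 nm height precision at 30 Hz from 8-bit images.

There is also a CLI:

```bash
phasortrack simulate --protocol methods-3600 --seed 7 --out stack.tif
phasortrack calibrate --stack ramp.tif --truth ramp.tif.truth.csv --out cal.json
phasortrack track --stack stack.tif --calibration cal.json --out track.csv
phasortrack benchmark --grid fig5 --frames 600 --out table.csv
phasortrack steps --curve curve.csv --substrate-bp 2000 --out steps.json
```

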