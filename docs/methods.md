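# Methods

## The measurement being simulated

A transmission finger probe holds one LED-like emitter against the skin
and a detector diametrically opposite.  Two fluorescence channels (a
700-nm-band control dye and an 800-nm-band targeted conjugate) are read
out at 20 Hz for 300 minutes after co-injection.  Only the arterial
compartment changes volume at the heart rate, so the cardiac line in the
detected signal is proportional to the arterial agent concentration.
Tracking its amplitude in one-minute windows gives each agent's plasma
input function (PIF) **up to an unknown scale** — the method is inherently
relative.  The two relative PIFs drive a deconvolution correction of the
control-agent tissue curve inside the simplified reference tissue model
(SRTM), whose binding-potential (BP) parameter is the scientific target.

## Kinetic models and parameters

| parameter | value | units | role |
|---|---|---|---|
| targeted PIF | 0.95·e^(−0.23t) + 0.48·e^(−0.0026t) | µM, t min | plasma drive |
| control PIF | 5.2·e^(−0.22t) + 0.35·e^(−0.0042t) | µM | plasma drive |
| K₁ | 0.1 | min⁻¹ | blood→tissue influx |
| k₂ | 0.08 | min⁻¹ | tissue→blood efflux |
| kon | 0.05 | min⁻¹·(conc unit)⁻¹ | association |
| koff | 0.12 | min⁻¹ | dissociation |
| Bmax | 10 | conc unit | available receptor |
| heart rate | 60 | bpm | cardiac frequency |
| α | 0.116 | — | fractional arterial volume excursion |
| sampling | 20 Hz, 300 min | — | 360 001 samples/channel |

Two unit conventions deserve emphasis:

* **Rate constants are per minute.**  K₁ and k₂ are sometimes quoted with
  length-like units in the source literature; dimensional consistency of
  the compartment ODEs requires min⁻¹ and that is what is implemented.
* **One common concentration unit.**  The receptor parameters (kon, Bmax)
  are used as plain numbers alongside the µM-valued PIFs, i.e. all
  concentrations live in a single nominal unit.  Converting Bmax = 10 nM
  strictly to µM would make the bound pool (≤ 0.01 µM) invisible against
  µM-scale free concentrations and the binding study degenerate; the
  parameter set is only meaningful — and only reproduces the regime the
  method was designed for, with Cb excursions a sizeable fraction of
  Bmax — in the common-unit reading.

The one-compartment solution is evaluated in closed form (exact for
bi-exponential inputs); the saturable tumor system is integrated with an
adaptive Dormand–Prince Runge–Kutta method (rtol 1e-8, atol 1e-10), so
solver error is negligible against the injected noise.  Both are
cross-checked in the tests against independent stiff-ODE and fixed-step
RK4 integrations.

## Relative concentration units in the BP study

SRTM BP is **not** invariant to a relative rescaling of the two channels:
if the target curve is scaled by c relative to the control, the optimum
moves to BP′ = c·(1+BP) − 1 (the model is linear in the reference curve,
so a relative scale cannot be absorbed by R₁ alone).  Because PAF-PDD
measures only relative PIF shapes, the whole tumor study is conducted in
**relative concentration units**: every tissue curve is divided by its own
agent's peak plasma concentration, and the deconvolution kernel is
estimated from the max-normalised PIF shapes.  The kernel then carries the
inter-channel scale, so the corrected control curve lands in the targeted
channel's relative units and all four fitting cases are commensurable.
The uncorrected ("no deconvolution") case inherits the full scale-plus-
shape mismatch of the control PIF, which is exactly why its BP is
catastrophically biased — the effect the method exists to remove.

Shot noise for the tumor curves is applied in the count domain (channel
maximum scaled to 2¹⁵ for a 16-bit detector, Poisson draw) and converted
back to relative units, so noise injection does not disturb the unit
convention.

## Photon transport and the sensitivity weights

The finger is a 2-cm-diameter, 1-cm-long cylinder of concentric layers
(epidermis 0.15 cm, dermis 0.15 cm, muscle 0.2 cm, bone core) with two
0.08-cm arterial vessels along its axis on the dermis/muscle interface,
placed symmetrically about the mid-sagittal plane and, by default, close
to the illuminated surface — the probe is positioned over the palmar
digital arteries, which is the whole point of a PDD instrument.  Optical
properties are 800-nm literature values per layer with Henyey–Greenstein
anisotropy g = 0.9; boundaries are refractive-index matched (no Fresnel
reflection).  Both channels share one property set; per-channel overrides
are accepted in configuration.

The Monte Carlo is a weighted voxel walker: scattering lengths are drawn
from the local μs, absorption attenuates the weight continuously along
each sub-voxel track, and the track-length estimator accumulates fluence
(well defined also in μa = 0 voxels).  It is validated against energy
conservation, a 1/n variance law, and the infinite-medium diffusion
solution (agreement within a few per cent beyond three transport mean
free paths).  Identical seeds give bit-identical fluence volumes.  The
detector sensitivity profile is the excitation fluence rotated 180° about
the y axis — equivalent, for the rotation-invariant default geometry, to
re-simulating a source on the detector side (checked statistically in the
tests).  The Jacobian is the voxel-wise product of the two profiles.
Vessel pulsation enters as a proportional scaling of the arterial optical
properties with relative vessel volume (diameter², 0.786–0.832 mm about a
0.8-mm mean, fixing α ≈ 0.116), and, in the forward signal, as an
optional cosine modulation of the ROI weights interpolated between the
two extreme states.

**Two-weight mode.**  The forward model only consumes the ROI-summed
weights (W_art, W_tis), so an analytic mode takes them directly from
configuration.  The defaults (0.3, 1.0) describe a probe whose arterial
sensitivity is a sizeable fraction of the total — the pulsatile
component is then ≈ 5–7 % of full scale, the upper range of the clinical
perfusion index and the regime in which a PDD instrument is designed to
operate.  On the nominal deep-transmission geometry above, the desk-scale
Monte Carlo yields a far smaller ratio (W_art/W_tis ≈ 5×10⁻³ for any
vessel placement we scanned): with 800-nm epidermis absorption of
10 cm⁻¹ on both faces, little light crosses 2 cm of finger and the
artery never dominates the adjoint product.  In that regime the cardiac
line survives 16-bit noise but is quantised away at 8–10 bits; the
bundled defaults deliberately describe the favourable-coupling regime so
that the bit-depth study spans informative noise levels.  Both modes are
exposed (`mode="two_weight" | "mc"`).

## Noise model

Counts are scaled so the channel maximum sits at the half-maximum of the
detector bit depth (2^(bits−1)), then Poisson-sampled (shot noise), then
a Gaussian term is added with SD = `gauss_sigma_rel` × SD of the first
one-minute segment of the scaled signal, then rounded to integers
(quantisation).  `gauss_sigma_rel` defaults to 0.01 and can be calibrated
from any user-supplied plethysmography trace: a one-minute segment is
detrended with a 4th-degree polynomial and the residual SD, relative to
the segment SD, is taken as the noise level.  The polynomial cannot
follow the cardiac oscillation, so this calibration deliberately counts
all sub-minute variation as noise.

## PIF reconstruction choices

* 60-s rectangular windows at 20 Hz put the 1-Hz cardiac line exactly on
  an FFT bin; the amplitude is read from that single bin (no multi-bin
  integration).
* The peak is selected by largest complex **magnitude** within a
  0.5–3 Hz physiologic band.  A largest-real-part criterion is available
  behind a flag, but the real part depends on the arbitrary phase of the
  cardiac cycle at each window start, so magnitude is the default.
* Each window is detrended with a 4th-degree polynomial before the FFT.
  Early after injection the tissue signal ramps quickly and the spectral
  leakage of that ramp otherwise biases the cardiac bin; detrending
  removes it while leaving a 60-cycle oscillation untouched.  Without
  this step the noise-free end-to-end reconstruction error is ~10⁻³
  (mean-squared, normalised units) instead of < 10⁻⁴.
* Heart rate is constant at 60 bpm; no heart-rate tracking is
  implemented.
* The reconstruction is normalised to its maximum and timestamped at
  window centres; comparisons against true shapes use the same grid.

## Deconvolution and SRTM fitting

The kernel g is estimated by pseudo-inverting the causal lower-triangular
Toeplitz convolution matrix of the control PIF through a truncated SVD;
singular values below 0.02 of the largest are discarded for noisy
(reconstructed) inputs, and no truncation is used for analytic inputs.
Discrete convolutions with g use the rectangle rule (consistent with the
Toeplitz construction); the exponential kernel inside the SRTM uses the
trapezoid rule at the 1-min grid.  The SRTM is fitted by bounded
trust-region least squares for (R₁, k₂, BP) with bounds (0, 10], (0, 1],
(0, 100], initial point (1, 0.1, 1) and two fixed rescaled restarts to
guard against local minima; fits are deterministic given inputs.

## What the synthetic data do and do not emulate

The generators reproduce bi-exponential plasma kinetics with cardiac
modulation, compartmental tissue uptake with saturable binding, detector
count statistics and quantisation.  They do not emulate heart-rate
variability, motion artifacts, wavelength-dependent optical properties,
probe-coupling drift, or inter-subject kinetic variability.  Passing
tests therefore demonstrate internal consistency of the measurement
principle and of the correction chain under ideal periodic physiology,
not robustness to the artifacts a clinical device would face.

## Known limitations and observed behaviour

* The PDD-corrected BP carries a small positive bias (≈ +1 % relative to
  the true-PIF correction) from the SVD truncation and the positive
  rectification bias of spectral-amplitude estimates under noise.  With
  ten replicates the paired t-test resolves this bias as significant even
  though it is practically negligible; the no-correction bias it stands
  against is three orders of magnitude larger.
* BP values depend on the per-channel unit convention (see above); the
  package reports them in relative concentration units throughout.
* The replicate count behind all ± values defaults to 10; standard
  deviations (not means) are sensitive to this choice.
* Absolute PIF quantification is out of scope: the method yields relative
  shapes only.
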