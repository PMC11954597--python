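# pafpdd — paired-agent fluorescence pulse-dye densitometry

Quantitative paired-agent imaging (PAI) co-administers a molecularly
**targeted** fluorescent agent with an untargeted **control** agent and
divides out non-specific delivery to estimate the **binding potential**
(BP), a quantity proportional to the concentration of the targeted
receptor.  Accurate BP estimation requires correcting for differences in
the two agents' **plasma input functions** (PIFs).  `pafpdd` simulates and
analyses a non-invasive way to measure those PIFs: a two-channel
finger-probe fluorescence system in the spirit of a pulse oximeter.  Only
arterial blood pulses at the cardiac frequency, so the amplitude of the
cardiac spectral line in the detected fluorescence tracks the plasma
concentration of each agent — pulse-dye densitometry (PDD) extended to
paired fluorescent agents (PAF-PDD).

The package is aimed at researchers in diffuse optics and tracer-kinetic
modelling who want to explore probe design (detector bit depth, noise,
geometry) and its downstream effect on kinetic-parameter recovery.

## Model

* **PIFs** are bi-exponential fits to population blood-draw data,
  `Cp(t) = a₁·e^(−r₁t) + a₂·e^(−r₂t)`; the bundled targeted/control pair is
  `0.95·e^(−0.23t) + 0.48·e^(−0.0026t)` µM and
  `5.2·e^(−0.22t) + 0.35·e^(−0.0042t)` µM (t in minutes).
* **Cardiac modulation**: `Cp(t)·(1 + (α/2)·sin 2πft)` with f = 1 Hz
  (60 bpm) and α ≈ 0.116 the fractional arterial volume excursion.
* **Tissue kinetics**: a one-tissue compartment
  `dCf/dt = K₁Cp − k₂Cf` for non-binding uptake, and a saturable
  free + bound tumor model
  `dCb/dt = kon(Bmax − Cb)Cf − koff·Cb` for the targeted agent
  (K₁ = 0.1, k₂ = 0.08 min⁻¹, kon = 0.05, koff = 0.12, Bmax = 10).
* **Photon transport**: a voxel Monte Carlo (Henyey–Greenstein scattering,
  track-length fluence estimator) over a layered-cylinder finger; the
  adjoint product of excitation and detection fluence gives the Jacobian
  weighting each voxel's contribution to the detected signal.  A fast
  two-weight mode replaces the Jacobian by its arterial/tissue ROI sums.
* **Signal and noise**: `S(t) = Iex·η·ε·[J_art·Cp(t) + J_tis·Cf(t)]`,
  sampled at 20 Hz for 300 min, scaled to the half-maximum of the detector
  bit depth, Poisson (shot) noise, pleth-calibrated additive Gaussian
  noise, integer quantisation.
* **PIF reconstruction**: per 1-min window, FFT and extraction of the
  dominant cardiac-band line amplitude; the window series, max-normalised,
  is the relative PIF.
* **Correction and fitting**: a kernel g with
  `Cp_tar = Cp_con ⊛ g` estimated by truncated-SVD deconvolution, and the
  simplified reference tissue model (SRTM)
  `Ctar = R₁·C + [k₂ − R₁k₂/(1+BP)]·C ⊛ e^(−k₂t/(1+BP))`, `C = Ccon ⊛ g`,
  fitted by bounded nonlinear least squares for (R₁, k₂, BP).

## Worked example

Four-case binding-potential study (equivalent PIFs; differing PIFs with
no / true-PIF / PDD-reconstructed deconvolution correction), five noise
replicates:

```python
from pafpdd import ExperimentConfig, run_bp_comparison

cfg = ExperimentConfig(replicates=5, seed=7)
df = run_bp_comparison(cfg)
print(df.groupby("case")[["BP", "relative_error"]].agg(["mean", "std"]).round(4))
```

```
                     BP         relative_error
                   mean     std           mean     std
case
equivalent       3.5730  0.0046         0.0000  0.0013
no_deconv       27.3841  0.0597         6.6642  0.0167
pafpdd_deconv    3.7301  0.0340         0.0440  0.0095
perfect_deconv   3.6777  0.0075         0.0293  0.0021
```

Reading the table: when both agents share a PIF the SRTM fit of the noisy
tumor curves gives the reference BP ≈ 3.57.  Ignoring the PIF difference
inflates BP roughly eight-fold (relative error ≈ 670 %).  Correcting with
the kernel deconvolved from the true PIF shapes — or from the PIF shapes
reconstructed end-to-end by the pulsatile two-channel measurement —
restores BP to within a few per cent of the reference, which is the
feasibility claim of the method.

The same study is available from the shell:

```bash
pafpdd bp-compare --seed 7 --outdir results
pafpdd bitdepth-sweep --seed 7 --outdir results
pafpdd mc-jacobian --n-photons 500000 --outdir results
```

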