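"""Forward synthesis of the detected fluorescence signal, filtering and noise.

The detected signal of a channel is the sensitivity-weighted sum of the
arterial (pulsatile plasma) and extravascular (tissue) agent concentrations,

    S(t) = Iex · η · ε · [ J_art(t) · Cp(t) + J_tis(t) · Cf(t) ],

with J_art, J_tis the ROI-summed Jacobian weights.  Detection adds shot
noise (Poisson, after scaling the channel maximum to the half-maximum of
the detector bit depth), a small additive Gaussian term calibrated against
plethysmography data, and integer quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries
from .pif_kinetics import PulsatileConfig

__all__ = [
    "AgentOptics",
    "NoiseModel",
    "WeightModulation",
    "synthesize_signal",
    "remove_dc",
    "add_noise",
    "calibrate_pleth_sigma",
]


@dataclass(frozen=True)
class AgentOptics:
    """Fluorophore photophysics for one detection channel.

    ``eta`` is the fluorescence quantum yield, ``epsilon`` the molar
    extinction coefficient (M⁻¹ cm⁻¹) at the excitation wavelength.  Only
    the product η·ε enters the signal; reconstructed input functions are
    later max-normalised, so the default product of 1 is a pure
    convention.
    """

    eta: float = 1.0
    epsilon: float = 1.0
    channel: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("quantum yield eta must lie in (0, 1]")
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise settings.

    ``bit_depth``: detector dynamic range in bits; the channel maximum is
    scaled to the half-maximum 2^(bit_depth−1) before Poisson sampling.
    Physical detectors span 8–16 bits; larger values are accepted as
    vanishing-noise limits.
    ``gauss_sigma_rel``: additive Gaussian noise SD relative to the signal
    variation scale (SD of the first one-minute segment of the scaled
    signal), as calibrated from a plethysmography trace.
    """

    bit_depth: int = 16
    gauss_sigma_rel: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4 <= self.bit_depth <= 48:
            raise ValueError("bit_depth out of supported range [4, 48]")
        if self.gauss_sigma_rel < 0:
            raise ValueError("gauss_sigma_rel must be non-negative")


@dataclass(frozen=True)
class WeightModulation:
    """Cardiac modulation of the ROI weights.

    Models the change of the Jacobian with vessel dilation by interpolating
    the ROI weights between their extreme (max/min vessel volume) states
    along the cosine volume waveform:

        J(t) = J0 · (1 + beta · cos(2π f t + phase)).

    ``beta_artery``/``beta_tissue`` are half the peak-to-peak relative
    excursions of the two ROI sums.  Zero (default) keeps the Jacobian
    static so the cardiac signal comes from the plasma concentration alone.
    """

    beta_artery: float = 0.0
    beta_tissue: float = 0.0
    phase: float = 0.0


def synthesize_signal(sensitivity, cp: TimeSeries, cf: TimeSeries,
                      optics: AgentOptics, cfg: PulsatileConfig,
                      modulation: WeightModulation | None = None) -> TimeSeries:
    """Detected fluorescence signal for one channel.

    Parameters
    ----------
    sensitivity : SensitivityMap or TwoWeightSensitivity
        Anything exposing ``roi_weights() -> (W_art, W_tis)`` and a
        ``source_intensity`` attribute.
    cp : pulsatile plasma concentration (from :func:`modulate_pif`).
    cf : extravascular tissue concentration, same grid as ``cp``.
    optics : channel photophysics.
    cfg : pulsatile/sampling configuration (defines the grid and cardiac
        frequency used for optional weight modulation).
    modulation : optional cardiac Jacobian modulation (default: static).
    """
    cp.require_same_grid(cf)
    w_art, w_tis = sensitivity.roi_weights()
    iex = getattr(sensitivity, "source_intensity", 1.0)
    gain = iex * optics.eta * optics.epsilon
    if modulation is not None and (modulation.beta_artery or modulation.beta_tissue):
        t_s = cp.t * (60.0 if cp.time_unit == "min" else 1.0)
        carrier = np.cos(2 * np.pi * cfg.heart_rate_hz * t_s + modulation.phase)
        j_art = w_art * (1.0 + modulation.beta_artery * carrier)
        j_tis = w_tis * (1.0 + modulation.beta_tissue * carrier)
    else:
        j_art, j_tis = w_art, w_tis
    s = gain * (j_art * cp.values + j_tis * cf.values)
    return cp.with_values(s, label=f"S_{optics.channel or cp.label}")


def remove_dc(s: TimeSeries, cutoff_hz: float = 10.0) -> TimeSeries:
    """Low-pass at ``cutoff_hz`` and remove the DC offset, by FFT masking.

    The DC bin is zeroed (so the output is exactly zero-mean) and all bins
    above the cutoff are zeroed; components in the passband — in
    particular the cardiac line — pass with unit gain.
    """
    dt_s = s.dt * (60.0 if s.time_unit == "min" else 1.0)
    nyquist = 0.5 / dt_s
    if cutoff_hz > nyquist * (1 + 1e-12):
        raise ValueError(f"cutoff {cutoff_hz} Hz above Nyquist {nyquist} Hz")
    spec = np.fft.rfft(s.values)
    freqs = np.fft.rfftfreq(s.values.size, dt_s)
    spec[0] = 0.0
    spec[freqs > cutoff_hz] = 0.0
    out = np.fft.irfft(spec, n=s.values.size)
    return s.with_values(out, label=f"{s.label}_ac")


def _first_minute_samples(s: TimeSeries) -> int:
    per_min = 60.0 / (s.dt * (60.0 if s.time_unit == "min" else 1.0))
    return int(round(per_min))


def add_noise(s: TimeSeries, nm: NoiseModel) -> TimeSeries:
    """Scale to detector counts, apply shot + Gaussian noise, quantise.

    The channel maximum maps to 2^(bit_depth−1) counts; counts are drawn
    from a Poisson law with that mean, a Gaussian with
    SD = ``gauss_sigma_rel`` × SD(first 1-min scaled segment) is added,
    and the result is rounded to integer counts.  Deterministic for a
    fixed ``nm.seed``.
    """
    x = s.values
    if np.any(x < 0):
        raise ValueError("expected counts must be non-negative; remove_dc "
                         "should be applied after noise, not before")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    rng = np.random.default_rng(nm.seed)
    scale = 2.0 ** (nm.bit_depth - 1) / x.max()
    counts = rng.poisson(x * scale).astype(float)
    if nm.gauss_sigma_rel > 0:
        n_min = min(_first_minute_samples(s), counts.size)
        ref_sd = counts[:n_min].std()
        counts += rng.normal(0.0, nm.gauss_sigma_rel * ref_sd, counts.shape)
    counts = np.round(counts)
    out = s.with_values(counts, label=f"{s.label}_counts")
    out.meta = dict(s.meta, bit_depth=nm.bit_depth, count_scale=scale)
    return out


def calibrate_pleth_sigma(pleth: TimeSeries, degree: int = 4) -> float:
    """Relative Gaussian-noise level from a plethysmography trace.

    A one-minute segment is detrended with a polynomial of the given
    degree; the SD of the residuals, relative to the SD of the segment
    itself, is returned as ``gauss_sigma_rel``.

    Note the polynomial cannot follow the cardiac oscillation, so for a
    clean pleth trace the residual contains the cardiac ripple — the
    calibration deliberately treats all sub-minute variation as "noise".
    """
    n_min = _first_minute_samples(pleth)
    if pleth.values.size < n_min:
        raise ValueError("plethysmography trace must be at least one minute long")
    seg = pleth.values[:n_min]
    tt = np.linspace(0.0, 1.0, n_min)
    resid = seg - np.polyval(np.polyfit(tt, seg, degree), tt)
    sd = seg.std()
    if sd == 0:
        return 0.0
    return float(resid.std() / sd)
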