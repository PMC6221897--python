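"""Band-pass filtering, Hilbert phase/amplitude, binned power and the two
spectral baseline features (high-frequency activity and spectral tilt).

The filter is a zero-phase windowed-sinc FIR: the linear-phase kernel is
applied forward and backward, which squares its magnitude response and leaves
zero group delay — essential when instantaneous phase is the quantity of
interest. The forward-backward pass is realized as a single convolution with
the symmetric kernel conv(b, b) (identical response, FFT-based overlap-add
so long low-band kernels stay cheap on trial x channel stacks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import EpochSet

logger = logging.getLogger(__name__)


class InvalidBandError(ValueError):
    """Band edges invalid for the sampling rate."""


class InvalidBinError(ValueError):
    """Requested time bin falls outside the epoch."""


@dataclass(frozen=True)
class BandConfig:
    """A named frequency band with edges in Hz."""

    name: str
    low_edge: float
    high_edge: float

    def validate(self, sampling_rate: float) -> None:
        if not (0 < self.low_edge < self.high_edge < sampling_rate / 2):
            raise InvalidBandError(
                f"band {self.name} ({self.low_edge}-{self.high_edge} Hz) invalid "
                f"at sampling rate {sampling_rate} Hz"
            )


GAMMA = BandConfig("high_gamma", 70.0, 100.0)
LOW = BandConfig("low", 3.0, 12.0)


@dataclass
class PhaseTensor:
    """Instantaneous phase, trial x channel x time, radians in (-pi, pi]."""

    phase: np.ndarray
    sampling_rate: float
    times: np.ndarray
    channel_labels: list[str]
    band: BandConfig

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phase.shape[1]


def design_fir(band: BandConfig, sampling_rate: float) -> np.ndarray:
    """Hamming windowed-sinc band-pass kernel for one forward pass.

    Transition width per edge is max(25% of the edge frequency, 2 Hz), capped
    at the edge itself; kernel length follows the Hamming approximation
    3.3 / (transition / fs), forced odd for a type-I linear-phase filter.
    """
    band.validate(sampling_rate)
    trans = min(
        min(max(0.25 * band.low_edge, 2.0), band.low_edge),
        max(0.25 * band.high_edge, 2.0),
    )
    numtaps = int(np.ceil(3.3 * sampling_rate / trans))
    numtaps += 1 - numtaps % 2
    return sps.firwin(
        numtaps,
        [band.low_edge, band.high_edge],
        pass_zero=False,
        window="hamming",
        fs=sampling_rate,
    )


def _zero_phase_filter(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR along the last axis with odd-reflection padding."""
    kernel = np.convolve(taps, taps[::-1])
    half = len(kernel) // 2
    pad = min(half, data.shape[-1] - 1)
    # odd reflection about the end samples, as in scipy.signal.filtfilt
    left = 2 * data[..., :1] - data[..., 1 : pad + 1][..., ::-1]
    right = 2 * data[..., -1:] - data[..., -pad - 1 : -1][..., ::-1]
    padded = np.concatenate([left, data, right], axis=-1)
    shape = (1,) * (data.ndim - 1) + (-1,)
    out = sps.oaconvolve(padded, kernel.reshape(shape), mode="same", axes=-1)
    return out[..., pad : pad + data.shape[-1]]


def bandpass(epochs: EpochSet, band: BandConfig) -> EpochSet:
    """Zero-phase band-pass of every trial and channel.

    The buffer samples are kept: they absorb the filter's edge artifacts and
    are trimmed later by :func:`analytic_phase` / :func:`analytic_amplitude`.
    """
    taps = design_fir(band, epochs.sampling_rate)
    filtered = _zero_phase_filter(epochs.data, taps)
    return replace(epochs, data=filtered)


def analytic_phase(filtered: EpochSet, band: BandConfig) -> PhaseTensor:
    """Instantaneous phase of the analytic signal; buffer samples trimmed.

    The input must already be band-limited; phase of broadband data is
    ill-defined (warned, not raised).
    """
    analytic = sps.hilbert(filtered.data, axis=-1)
    phase = np.angle(analytic)
    nb = int(round(filtered.buffer * filtered.sampling_rate))
    sl = slice(nb, phase.shape[-1] - nb) if nb else slice(None)
    return PhaseTensor(
        phase=phase[..., sl],
        sampling_rate=filtered.sampling_rate,
        times=filtered.times[sl],
        channel_labels=list(filtered.channel_labels),
        band=band,
    )


def _bin_slices(times: np.ndarray, sampling_rate: float, bins) -> list[slice]:
    """Half-open [start, end) sample slices for bins given in ms re cue."""
    slices = []
    t0 = times[0]
    n = times.shape[0]
    for start_ms, end_ms in bins:
        i0 = int(round((start_ms / 1000.0 - t0) * sampling_rate))
        i1 = int(round((end_ms / 1000.0 - t0) * sampling_rate))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise InvalidBinError(f"bin ({start_ms}, {end_ms}) ms outside epoch")
        slices.append(slice(i0, i1))
    return slices


def band_power(filtered: EpochSet, bins) -> np.ndarray:
    """Mean signal power per (trial, bin, channel).

    Power is ``mean(|analytic|^2) / 2`` over the half-open bin — for a
    narrowband signal this equals its mean-square power, so a unit-amplitude
    sinusoid yields 0.5.
    """
    analytic = sps.hilbert(filtered.data, axis=-1)
    nb = int(round(filtered.buffer * filtered.sampling_rate))
    sl = slice(nb, analytic.shape[-1] - nb) if nb else slice(None)
    amp2 = np.abs(analytic[..., sl]) ** 2
    times = filtered.times[sl]
    slices = _bin_slices(times, filtered.sampling_rate, bins)
    out = np.stack([amp2[..., s].mean(axis=-1) / 2.0 for s in slices], axis=1)
    return out  # (trial, bin, channel)


def zscore_across_trials(power: np.ndarray) -> np.ndarray:
    """Z-score each (bin, channel) cell across the trial dimension.

    Uses the sample (n-1) standard deviation. Cells with zero variance map
    to 0 with a warning rather than NaN.
    """
    if power.shape[0] < 3:
        raise ValueError("z-scoring requires at least 3 trials")
    mean = power.mean(axis=0, keepdims=True)
    sd = power.std(axis=0, ddof=1, keepdims=True)
    zero = sd == 0
    if zero.any():
        logger.warning("zero across-trial variance in %d cell(s); z set to 0", int(zero.sum()))
    sd = np.where(zero, 1.0, sd)
    z = (power - mean) / sd
    return np.where(np.broadcast_to(zero, z.shape), 0.0, z)


def spectral_tilt(hfa_z: np.ndarray, low_z: np.ndarray) -> np.ndarray:
    """High-band minus low-band z-scored power, elementwise."""
    if hfa_z.shape != low_z.shape:
        raise ValueError(f"shape mismatch: {hfa_z.shape} vs {low_z.shape}")
    return hfa_z - low_z


def save_spectral_features(features: dict, bins, path) -> None:
    """Persist hfa_z / low_z / tilt arrays to HDF5 with bin coordinates."""
    import h5py

    with h5py.File(path, "w") as f:
        for key in ("hfa_z", "low_z", "tilt"):
            f.create_dataset(key, data=features[key])
        f.create_dataset("bin_edges", data=np.asarray(bins))


def load_spectral_features(path) -> tuple[dict, tuple]:
    import h5py

    with h5py.File(path, "r") as f:
        features = {k: f[k][()] for k in ("hfa_z", "low_z", "tilt")}
        bins = tuple(tuple(b) for b in f["bin_edges"][()])
    return features, bins


def spectral_features(epochs: EpochSet, bins, gamma: BandConfig = GAMMA, low: BandConfig = LOW):
    """HFA z-power, low-band z-power and spectral tilt for the given bins.

    Returns
    -------
    dict with arrays ``hfa_z``, ``low_z``, ``tilt``; each (trial, bin, channel).
    """
    hfa = zscore_across_trials(band_power(bandpass(epochs, gamma), bins))
    lowp = zscore_across_trials(band_power(bandpass(epochs, low), bins))
    return {"hfa_z": hfa, "low_z": lowp, "tilt": spectral_tilt(hfa, lowp)}
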