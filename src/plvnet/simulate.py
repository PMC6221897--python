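"""Ground-truthed synthetic sEEG sessions for a cued delayed-reaction task.

Each simulated session emulates an intracranial recording during a temporal
expectancy task: a visual cue, an instructed delay of 500 or 1500 ms (chosen
with equal probability), a go signal, and a speeded keypress. Every channel
carries three additive components, in microvolts:

* a 1/f^beta background (FFT-shaped Gaussian noise),
* a low-frequency oscillation at a per-channel frequency inside ``low_band``,
* a high-gamma oscillation whose instantaneous phase follows a session-wide
  common oscillator plus per-channel von Mises jitter.

The jitter is drawn on a coarse (default 50 ms) block grid and interpolated
smoothly between blocks, so it survives the narrow zero-phase band-pass that
precedes phase extraction instead of being averaged away. Its concentration
during the 500 ms *pre-cue* window of trial i is ``kappa_i * kappa_max``,
where ``kappa_i`` in [0, 1] is the trial's coupling strength, so the pre-cue
pairwise phase-locking value increases monotonically with ``kappa_i``. Coupling during the delay window is drawn independently of
``kappa_i`` (and of the reaction time), so only pre-cue connectivity carries
behavioural signal. Outside trial windows the jitter is uniform (no
coupling).

Reaction times follow a linear link with additive Gaussian noise,

    RT_i = r0 - r1 * kappa_i + eps_i,   eps_i ~ N(0, sigma^2),

truncated below at 100 ms. With ``r1 = 0`` the session is a behavioural null:
coupling still fluctuates trial to trial but is unrelated to RT.

Gamma amplitude is drawn per trial per channel from a log-normal, so power-
and phase-based features are dissociable by construction: a strongly coupled
trial need not be a high-power trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io import EVENT_COLUMNS, Recording, write_edf

logger = logging.getLogger(__name__)

RT_FLOOR_MS = 100.0


class InvalidConfigError(ValueError):
    """Simulator configuration outside its valid ranges."""


class AliasingError(InvalidConfigError):
    """Sampling rate too low for the configured gamma band."""


@dataclass
class SimConfig:
    """Configuration of one synthetic session.

    Parameters
    ----------
    n_channels, n_trials : int
        Network nodes and task trials. Defaults emulate the 122-contact
        recording and a session long enough to leave ~57 analyzable
        1500-ms-delay trials.
    sampling_rate : float
        Hz; must be at least 2 x 1.25 x the upper gamma edge.
    delay_options : tuple of float
        Instructed delay durations in ms, chosen with equal probability.
    gamma_band, low_band : (low, high) Hz
        Coupled high-gamma band and low-frequency background oscillation band.
    coupling_range : (lo, hi) in [0, 1]
        Per-trial coupling kappa_i ~ Uniform(lo, hi).
    kappa_max : float
        Von Mises concentration at kappa = 1 (may be ``np.inf`` for zero
        jitter, i.e. perfectly locked phases).
    jitter_block_s : float
        Spacing (s) of the jitter block grid; jitter is interpolated
        between blocks so phase noise is smooth on the filter's time scale.
    rt_intercept_ms, rt_slope_ms, rt_noise_sd_ms : float
        r0, r1 and sigma of the RT link. Defaults give a true
        kappa-RT correlation of about -0.5 (r1 = 2 sigma, kappa uniform).
    background_exponent : float
        beta of the 1/f^beta background power spectrum.
    background_sd_uv, low_amp_uv, gamma_amp_uv : float
        Component scales in microvolts.
    trial_spacing_s, session_padding_s : float
        Cue-to-cue interval and silent padding at both session ends.
    seed : int
        Master seed; the whole session is bit-reproducible given the config.
    """

    n_channels: int = 122
    n_trials: int = 114
    sampling_rate: float = 512.0
    delay_options: tuple[float, ...] = (500.0, 1500.0)
    gamma_band: tuple[float, float] = (70.0, 100.0)
    low_band: tuple[float, float] = (3.0, 12.0)
    coupling_range: tuple[float, float] = (0.0, 1.0)
    kappa_max: float = 4.0
    jitter_block_s: float = 0.05
    rt_intercept_ms: float = 350.0
    rt_slope_ms: float = 100.0
    rt_noise_sd_ms: float = 50.0
    background_exponent: float = 2.0
    background_sd_uv: float = 10.0
    low_amp_uv: float = 20.0
    gamma_amp_uv: float = 15.0
    gamma_amp_sigma: float = 0.3
    precue_window_s: float = 0.5
    coupling_pad_s: float = 0.2
    trial_spacing_s: float = 3.2
    session_padding_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.n_trials < 1:
            raise InvalidConfigError("n_channels and n_trials must be positive")
        if self.sampling_rate < 2.0 * self.gamma_band[1] * 1.25:
            raise AliasingError(
                f"sampling_rate {self.sampling_rate} Hz is below "
                f"{2.5 * self.gamma_band[1]:.0f} Hz required for the "
                f"{self.gamma_band} Hz band"
            )
        lo, hi = self.coupling_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise InvalidConfigError("coupling_range must lie within [0, 1]")
        if not self.delay_options:
            raise InvalidConfigError("delay_options must be non-empty")
        if self.kappa_max < 0:
            raise InvalidConfigError("kappa_max must be non-negative")


@dataclass
class GroundTruth:
    """Per-trial latent variables of a simulated session."""

    kappa: np.ndarray          # pre-cue coupling, [0, 1]
    rt_ms: np.ndarray          # realized reaction time
    delay_ms: np.ndarray       # instructed delay
    cue_time_s: np.ndarray     # cue onsets on the sample grid
    gamma_freq_hz: float       # common oscillator frequency
    gamma_phase0: float        # common oscillator phase at t = 0
    kappa_delay: np.ndarray = field(default=None)  # delay-window coupling

    def oscillator_phase(self, t: np.ndarray) -> np.ndarray:
        """Common-oscillator phase at times ``t`` (s), wrapped to (-pi, pi]."""
        phase = 2 * np.pi * self.gamma_freq_hz * t + self.gamma_phase0
        return np.angle(np.exp(1j * phase))


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent, unit-free sd."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spectrum * scale, n)
    return shaped * (sd / shaped.std())


def _von_mises_jitter(
    rng: np.random.Generator,
    kappa_profile: np.ndarray,
    n_channels: int,
    block_samples: int,
) -> np.ndarray:
    """Smooth per-channel phase jitter with von Mises marginals.

    Angles are drawn independently per channel on a block grid (concentration
    taken from ``kappa_profile`` at the block anchor, inf = zero jitter) and
    interpolated between blocks through their unit phasors, keeping the
    jitter smooth on the band-pass filter's time scale.
    """
    n_samples = kappa_profile.shape[0]
    anchors = np.arange(0, n_samples + block_samples, block_samples)
    conc = kappa_profile[np.minimum(anchors, n_samples - 1)]
    finite = np.isfinite(conc)
    angles = np.zeros((n_channels, anchors.size))
    if finite.any():
        angles[:, finite] = rng.vonmises(0.0, conc[finite], size=(n_channels, int(finite.sum())))
    t = np.arange(n_samples)
    out = np.empty((n_channels, n_samples))
    for ch in range(n_channels):
        c = np.interp(t, anchors, np.cos(angles[ch]))
        s = np.interp(t, anchors, np.sin(angles[ch]))
        out[ch] = np.arctan2(s, c)
    return out


def simulate_session(config: SimConfig) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Simulate one task session.

    Returns
    -------
    recording : Recording
        Continuous multichannel signal, microvolts.
    events : DataFrame
        One row per trial: trial_id, cue_time_s, delay_ms, go_time_s,
        keypress_time_s.
    truth : GroundTruth
        The latent coupling, RTs and oscillator parameters that generated it.
    """
    config.validate()
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)

    # --- behaviour -------------------------------------------------------
    delays = rng.choice(np.asarray(config.delay_options, dtype=float), size=config.n_trials)
    kappa = rng.uniform(*config.coupling_range, size=config.n_trials)
    kappa_delay = rng.uniform(*config.coupling_range, size=config.n_trials)
    eps = rng.normal(0.0, config.rt_noise_sd_ms, size=config.n_trials)
    rt = np.maximum(RT_FLOOR_MS, config.rt_intercept_ms - config.rt_slope_ms * kappa + eps)

    cue_samples = (
        np.round(
            (config.session_padding_s + config.trial_spacing_s * np.arange(config.n_trials)) * fs
        ).astype(int)
    )
    cue_times = cue_samples / fs
    go_times = cue_times + delays / 1000.0
    keypress_times = go_times + rt / 1000.0
    # store the RT the event table reproduces bit-exactly on re-derivation
    rt = (keypress_times - go_times) * 1000.0

    n_samples = int(round((cue_times[-1] + config.trial_spacing_s + config.session_padding_s) * fs))
    n_samples = int(np.ceil(n_samples / fs) * fs)  # whole seconds, EDF-friendly
    t = np.arange(n_samples) / fs

    # --- per-sample jitter concentration profile -------------------------
    # uniform jitter (kappa_vm = 0) outside trial windows
    kappa_vm = np.zeros(n_samples)
    pre_n = int(round(config.precue_window_s * fs))

    def conc(k: float) -> float:
        # k * kappa_max, well-defined for kappa_max = inf
        if not np.isfinite(config.kappa_max):
            return np.inf if k > 0 else 0.0
        return k * config.kappa_max

    # coupled windows are padded outward by coupling_pad_s so the band-pass
    # kernel does not smear uncoupled flanking signal into the analysis bins
    pad_n = int(round(config.coupling_pad_s * fs))
    for i in range(config.n_trials):
        c = cue_samples[i]
        d_n = int(round(delays[i] / 1000.0 * fs))
        kappa_vm[max(c - pre_n - pad_n, 0) : c] = conc(kappa[i])
        kappa_vm[c : min(c + d_n + pad_n, n_samples)] = conc(kappa_delay[i])

    # --- common oscillator ----------------------------------------------
    f_gamma = float(np.mean(config.gamma_band))
    phase0 = float(rng.uniform(-np.pi, np.pi))
    common_phase = 2 * np.pi * f_gamma * t + phase0

    # per-trial x channel log-normal gamma amplitude (mean ~ gamma_amp_uv)
    sig = config.gamma_amp_sigma
    amp_factors = rng.lognormal(-0.5 * sig**2, sig, size=(config.n_trials, config.n_channels))
    amp = np.ones((config.n_channels, n_samples))
    span_n = int(round(config.trial_spacing_s * fs))
    for i in range(config.n_trials):
        c = cue_samples[i]
        amp[:, max(c - pre_n, 0) : min(c + span_n - pre_n, n_samples)] = amp_factors[i][:, None]
    # ~100 ms ramp between amplitude levels: a hard step at a trial boundary
    # would splash a broadband filter transient into the pre-cue bin
    ramp_n = max(1, int(round(0.1 * fs)))
    amp = uniform_filter1d(amp, size=ramp_n, axis=1, mode="nearest")

    samples = np.empty((config.n_channels, n_samples))
    block_n = max(1, int(round(config.jitter_block_s * fs)))
    jitter = _von_mises_jitter(rng, kappa_vm, config.n_channels, block_n)
    low_freqs = rng.uniform(*config.low_band, size=config.n_channels)
    low_phases = rng.uniform(-np.pi, np.pi, size=config.n_channels)
    for ch in range(config.n_channels):
        bg = _one_over_f(rng, n_samples, fs, config.background_exponent, config.background_sd_uv)
        low = config.low_amp_uv * np.cos(2 * np.pi * low_freqs[ch] * t + low_phases[ch])
        gamma = config.gamma_amp_uv * amp[ch] * np.cos(common_phase + jitter[ch])
        samples[ch] = bg + low + gamma

    recording = Recording(
        samples=samples,
        sampling_rate=fs,
        channel_labels=[f"CH{i:03d}" for i in range(config.n_channels)],
    )
    events = pd.DataFrame(
        {
            "trial_id": np.arange(config.n_trials),
            "cue_time_s": cue_times,
            "delay_ms": delays,
            "go_time_s": go_times,
            "keypress_time_s": keypress_times,
        }
    )
    truth = GroundTruth(
        kappa=kappa,
        rt_ms=rt,
        delay_ms=delays,
        cue_time_s=cue_times,
        gamma_freq_hz=f_gamma,
        gamma_phase0=phase0,
        kappa_delay=kappa_delay,
    )
    return recording, events, truth


def write_session(
    recording: Recording, events: pd.DataFrame, path, truth: GroundTruth | None = None
) -> dict[str, str]:
    """Write a session to ``path`` as EDF + CSV event table (+ ground truth).

    Returns a dict of the file paths written, keys ``edf``, ``events`` and,
    when ``truth`` is given, ``ground_truth``.
    """
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {"edf": str(path / "session.edf"), "events": str(path / "events.csv")}
    write_edf(recording, files["edf"])
    events.loc[:, list(EVENT_COLUMNS)].to_csv(files["events"], index=False)
    if truth is not None:
        files["ground_truth"] = str(path / "ground_truth.csv")
        pd.DataFrame(
            {
                "trial_id": np.arange(len(truth.kappa)),
                "kappa": truth.kappa,
                "rt_ms": truth.rt_ms,
                "delay_ms": truth.delay_ms,
            }
        ).to_csv(files["ground_truth"], index=False)
    return files
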