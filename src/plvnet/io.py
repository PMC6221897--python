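"""Reading, writing and epoching of continuous recordings and event tables.

Recordings travel as :class:`Recording` (channels x time, microvolts); trial
events as :class:`EventTable` (one row per trial with cue/go/keypress times);
epoched data as :class:`EpochSet` (trial x channel x time aligned to cue).

Times are in seconds, the cue is at t = 0, and sample bins are half-open
[start, end) throughout, so a window of (-0.5, 1.5) s at 1000 Hz contains
exactly 2000 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("trial_id", "cue_time_s", "delay_ms", "go_time_s", "keypress_time_s")


class FormatError(ValueError):
    """Malformed or unsupported file content."""


@dataclass
class Recording:
    """Continuous multichannel recording.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    sampling_rate : float
        Hz, shared by all channels.
    channel_labels : list of str
        Unique channel names.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i:03d}" for i in range(self.samples.shape[0])]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.sampling_rate


@dataclass
class EpochSet:
    """Trial x channel x time tensor aligned to cue onset.

    ``times`` holds seconds relative to cue; a non-zero ``buffer`` means the
    tensor still carries extra samples on both sides for filter edge handling,
    to be trimmed after phase/amplitude extraction.
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    channel_labels: list[str]
    rts: np.ndarray
    trial_ids: np.ndarray
    delay_ms: float
    buffer: float = 0.0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def trim_buffer(self) -> "EpochSet":
        """Drop the buffer samples, returning an EpochSet with buffer = 0."""
        if self.buffer == 0:
            return self
        nb = int(round(self.buffer * self.sampling_rate))
        return replace(
            self,
            data=self.data[:, :, nb : self.data.shape[2] - nb],
            times=self.times[nb : self.times.shape[0] - nb],
            buffer=0.0,
        )


def read_events(path) -> pd.DataFrame:
    """Read a trial event table from CSV.

    Expects columns ``trial_id, cue_time_s, delay_ms, go_time_s,
    keypress_time_s``. Adds a derived ``rt_ms`` column, sorts rows by cue
    time, and drops rows whose keypress precedes the go signal (logged).

    Returns
    -------
    DataFrame with the five input columns plus ``rt_ms``.
    """
    events = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    events = events.sort_values("cue_time_s", kind="stable").reset_index(drop=True)
    events["rt_ms"] = (events["keypress_time_s"] - events["go_time_s"]) * 1000.0
    bad = events["rt_ms"] <= 0
    if bad.any():
        logger.warning("excluding %d trial(s) with keypress at or before go", int(bad.sum()))
        events = events.loc[~bad].reset_index(drop=True)
    return events


def epoch(
    recording: Recording,
    events: pd.DataFrame,
    window: tuple[float, float] = (-0.5, 1.5),
    delay_filter: float | None = 1500.0,
    buffer: float = 0.5,
) -> EpochSet:
    """Cut cue-aligned epochs out of a continuous recording.

    Parameters
    ----------
    window : (start, end) in seconds relative to cue, half-open in samples.
    delay_filter : keep only trials whose instructed delay (ms) equals this;
        ``None`` keeps all trials.
    buffer : extra seconds kept on each side for filter edge artifacts.

    Trials whose padded window falls outside the recording are dropped with a
    warning. Raises ``ValueError`` if no trial survives.
    """
    fs = recording.sampling_rate
    if "rt_ms" not in events.columns:
        events = events.assign(
            rt_ms=(events["keypress_time_s"] - events["go_time_s"]) * 1000.0
        )
    if delay_filter is not None:
        events = events[np.isclose(events["delay_ms"], delay_filter)]
    n_samp = int(round((window[1] - window[0] + 2 * buffer) * fs))
    start_off = int(round((window[0] - buffer) * fs))

    kept, starts = [], []
    for row in events.itertuples(index=False):
        i0 = int(round(row.cue_time_s * fs)) + start_off
        if i0 < 0 or i0 + n_samp > recording.n_times:
            logger.warning("dropping trial %s: window outside recording", row.trial_id)
            continue
        kept.append(row)
        starts.append(i0)
    if not kept:
        raise ValueError("no trials retained after delay filtering / bounds checks")

    data = np.stack([recording.samples[:, i0 : i0 + n_samp] for i0 in starts])
    times = (np.arange(n_samp) + start_off) / fs
    return EpochSet(
        data=data,
        sampling_rate=fs,
        times=times,
        channel_labels=list(recording.channel_labels),
        rts=np.array([row.rt_ms for row in kept], dtype=float),
        trial_ids=np.array([row.trial_id for row in kept]),
        delay_ms=delay_filter if delay_filter is not None else np.nan,
        buffer=buffer,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _check_uniform_edf_rates(path) -> None:
    """Reject EDF files whose signal channels have unequal sampling rates
    (MNE would silently resample them)."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError("truncated EDF header")
        try:
            n_sig = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError("malformed EDF header") from exc
        sig = fh.read(n_sig * 256)
    labels = [sig[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip() for i in range(n_sig)]
    spr_off = n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    try:
        rates = {
            int(sig[spr_off + i * 8 : spr_off + (i + 1) * 8].decode("ascii").strip())
            for i in range(n_sig)
            if labels[i] != "EDF Annotations"
        }
    except ValueError as exc:
        raise FormatError("malformed EDF signal header") from exc
    if len(rates) > 1:
        raise FormatError(f"mixed per-channel sampling rates are unsupported: {sorted(rates)}")


def read_edf(path) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts).

    Goes through MNE's EDF reader; all channels must share one sampling rate.
    """
    import mne

    _check_uniform_edf_rates(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types for malformed files
        raise FormatError(f"could not read EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE returns volts for EEG channels
    return Recording(
        samples=data, sampling_rate=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names)
    )


def write_edf(
    recording: Recording,
    path,
    physical_range: tuple[float, float] | None = None,
    digital_range: tuple[int, int] = (-32768, 32767),
) -> None:
    """Write a :class:`Recording` as a standard 16-bit EDF file.

    One data record per second; the final partial second, if any, is
    zero-padded. Physical min/max default to each channel's data range
    (symmetric, with a small margin); pass ``physical_range`` to force a
    common calibration for all channels.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_t = recording.samples.shape
    n_rec = int(np.ceil(n_t / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, :n_t] = recording.samples

    dmin, dmax = digital_range
    if physical_range is not None:
        pmins = np.full(n_ch, float(physical_range[0]))
        pmaxs = np.full(n_ch, float(physical_range[1]))
    else:
        amp = np.max(np.abs(data), axis=1)
        amp = np.where(amp > 0, amp * 1.0001, 1.0)
        pmins, pmaxs = -amp, amp

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        (recording.channel_labels, 16),
        (["" for _ in range(n_ch)], 80),  # transducer
        (["uV"] * n_ch, 8),
        ([f"{v:.8g}"[:8] for v in pmins], 8),
        ([f"{v:.8g}"[:8] for v in pmaxs], 8),
        ([str(dmin)] * n_ch, 8),
        ([str(dmax)] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),  # prefiltering
        ([str(fs)] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]
    sig_header = b"".join(b"".join(pad(v, w) for v in values) for values, w in fields)

    gains = (dmax - dmin) / (pmaxs - pmins)
    digital = np.round((data - pmins[:, None]) * gains[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records are interleaved: per record, all samples of ch0, then ch1, ...
        rec_view = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec_view).tobytes())


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path) -> None:
    """Persist an EpochSet to HDF5 (/data, /time_axis, /rts + attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time_axis", data=epochs.times)
        f.create_dataset("rts", data=epochs.rts)
        f.create_dataset("trial_ids", data=np.asarray(epochs.trial_ids, dtype=np.int64))
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["channel_labels"] = [str(c) for c in epochs.channel_labels]
        f.attrs["delay_ms"] = epochs.delay_ms
        f.attrs["buffer"] = epochs.buffer


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            times=f["time_axis"][()],
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
            rts=f["rts"][()],
            trial_ids=f["trial_ids"][()],
            delay_ms=float(f.attrs["delay_ms"]),
            buffer=float(f.attrs["buffer"]),
        )
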