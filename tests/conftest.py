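import numpy as np
import pandas as pd
import pytest

import plvnet
from plvnet.spectral import GAMMA


@pytest.fixture(scope="session")
def small_session():
    """A small simulated session with a strong coupling-RT link."""
    cfg = plvnet.SimConfig(
        n_channels=6, n_trials=24, sampling_rate=256.0, delay_options=(1500.0,), seed=7
    )
    recording, events, truth = plvnet.simulate_session(cfg)
    return cfg, recording, events, truth


@pytest.fixture(scope="session")
def small_epochs(small_session):
    _, recording, events, _ = small_session
    events = events.assign(rt_ms=(events.keypress_time_s - events.go_time_s) * 1000.0)
    return plvnet.epoch(recording, events)


@pytest.fixture(scope="session")
def small_phases(small_epochs):
    return plvnet.analytic_phase(plvnet.bandpass(small_epochs, GAMMA), GAMMA)


def sinusoid_epochs(freqs, amps=None, fs=1000.0, duration=2.0, buffer=0.5, n_trials=1):
    """EpochSet holding pure sinusoid channels (cue at t = 0)."""
    freqs = np.atleast_1d(freqs).astype(float)
    amps = np.ones_like(freqs) if amps is None else np.atleast_1d(amps).astype(float)
    n = int(round((duration + 2 * buffer) * fs))
    t = (np.arange(n) - int(round(buffer * fs))) / fs
    data = np.stack([a * np.cos(2 * np.pi * f * t) for f, a in zip(freqs, amps)])
    data = np.broadcast_to(data, (n_trials,) + data.shape).copy()
    return plvnet.EpochSet(
        data=data,
        sampling_rate=fs,
        times=t,
        channel_labels=[f"S{i}" for i in range(freqs.size)],
        rts=np.full(n_trials, 300.0),
        trial_ids=np.arange(n_trials),
        delay_ms=1500.0,
        buffer=buffer,
    )


def events_frame(cues, delays_ms, rts_ms):
    """Event table with consistent go/keypress columns."""
    cues = np.asarray(cues, dtype=float)
    delays_ms = np.broadcast_to(np.asarray(delays_ms, dtype=float), cues.shape)
    rts_ms = np.broadcast_to(np.asarray(rts_ms, dtype=float), cues.shape)
    go = cues + delays_ms / 1000.0
    return pd.DataFrame(
        {
            "trial_id": np.arange(cues.size),
            "cue_time_s": cues,
            "delay_ms": delays_ms,
            "go_time_s": go,
            "keypress_time_s": go + rts_ms / 1000.0,
            "rt_ms": rts_ms,
        }
    )
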