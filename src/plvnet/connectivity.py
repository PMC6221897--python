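"""Single-trial phase-locking-value adjacency matrices in sliding time bins.

The phase-locking value between channels i and j over the T samples of one
bin of one trial is

    PLV_ij = | (1/T) sum_t exp( i * (phi_i(t) - phi_j(t)) ) |,

i.e. the resultant length of the phase-difference phasor averaged over *time
samples within the trial*, not over trials. PLV is 1 for any constant phase
offset and near the finite-sample chance level (~ sqrt(pi) / (2 sqrt(T)))
for independent uniform phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .spectral import BandConfig, PhaseTensor, _bin_slices

logger = logging.getLogger(__name__)

MIN_BIN_SAMPLES = 32

#: The four contiguous 500-ms analysis bins: pre-cue, early-, mid-, late-delay.
DEFAULT_BINS = ((-500.0, 0.0), (0.0, 500.0), (500.0, 1000.0), (1000.0, 1500.0))


class TooFewSamplesError(ValueError):
    """A bin holds fewer samples than the PLV estimator allows."""


@dataclass
class ConnectivityTensor:
    """PLV adjacency per trial and bin.

    ``plv`` has shape (trial, bin, channel, channel), is symmetric in the
    last two axes, has a zero diagonal by convention, and all off-diagonal
    values lie in [0, 1].
    """

    plv: np.ndarray
    bin_edges: tuple[tuple[float, float], ...]
    band: BandConfig
    channel_labels: list[str]

    @property
    def n_trials(self) -> int:
        return self.plv.shape[0]

    @property
    def n_bins(self) -> int:
        return self.plv.shape[1]

    @property
    def n_channels(self) -> int:
        return self.plv.shape[2]


def sliding_bins(start_ms: float, end_ms: float, width_ms: float = 500.0, step_ms: float | None = None):
    """Sliding (start, end) bin edges in ms; default step = width (contiguous)."""
    step = width_ms if step_ms is None else step_ms
    edges = []
    s = start_ms
    while s + width_ms <= end_ms + 1e-9:
        edges.append((s, s + width_ms))
        s += step
    return tuple(edges)


def single_trial_plv(phases: PhaseTensor, bin_edges=DEFAULT_BINS) -> ConnectivityTensor:
    """PLV between all channel pairs, per trial and time bin.

    Parameters
    ----------
    phases : PhaseTensor
        Trial x channel x time instantaneous phase (buffer already trimmed).
    bin_edges : sequence of (start_ms, end_ms)
        Half-open bins relative to cue; each must hold >= 32 samples.
    """
    slices = _bin_slices(phases.times, phases.sampling_rate, bin_edges)
    for (s, e), sl in zip(bin_edges, slices):
        if sl.stop - sl.start < MIN_BIN_SAMPLES:
            raise TooFewSamplesError(
                f"bin ({s}, {e}) ms holds {sl.stop - sl.start} samples "
                f"(< {MIN_BIN_SAMPLES})"
            )
    if np.isnan(phases.phase).any():
        bad = np.argwhere(np.isnan(phases.phase).any(axis=-1))
        logger.warning("NaN phase in (trial, channel) pairs %s; PLV will be NaN", bad[:10].tolist())

    n_tr, n_ch, _ = phases.phase.shape
    out = np.empty((n_tr, len(slices), n_ch, n_ch))
    for b, sl in enumerate(slices):
        z = np.exp(1j * phases.phase[:, :, sl])
        T = sl.stop - sl.start
        # Gram matrix of unit phasors: C_ij = (1/T) sum_t z_i(t) conj(z_j(t))
        C = z @ z.conj().transpose(0, 2, 1) / T
        plv = np.abs(C)
        plv = 0.5 * (plv + plv.transpose(0, 2, 1))  # bitwise-exact symmetry
        idx = np.arange(n_ch)
        plv[:, idx, idx] = 0.0
        out[:, b] = plv
    out = np.clip(out, 0.0, 1.0)
    return ConnectivityTensor(
        plv=out,
        bin_edges=tuple(tuple(b) for b in bin_edges),
        band=phases.band,
        channel_labels=list(phases.channel_labels),
    )


def save_connectivity(conn: ConnectivityTensor, path) -> None:
    """Persist to HDF5: /plv and /bin_edges plus band/channel attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("plv", data=conn.plv)
        f.create_dataset("bin_edges", data=np.asarray(conn.bin_edges))
        f.attrs["band_name"] = conn.band.name
        f.attrs["band_edges"] = [conn.band.low_edge, conn.band.high_edge]
        f.attrs["channel_labels"] = [str(c) for c in conn.channel_labels]


def load_connectivity(path) -> ConnectivityTensor:
    with h5py.File(path, "r") as f:
        name = f.attrs["band_name"]
        lo, hi = f.attrs["band_edges"]
        return ConnectivityTensor(
            plv=f["plv"][()],
            bin_edges=tuple(tuple(b) for b in f["bin_edges"][()]),
            band=BandConfig(str(name), float(lo), float(hi)),
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
        )


def edge_list(conn: ConnectivityTensor, trial: int, bin_index: int) -> pd.DataFrame:
    """Upper-triangle edge list (node_i, node_j, weight) of one network."""
    A = conn.plv[trial, bin_index]
    i, j = np.triu_indices(A.shape[0], k=1)
    return pd.DataFrame(
        {
            "node_i": [conn.channel_labels[k] for k in i],
            "node_j": [conn.channel_labels[k] for k in j],
            "weight": A[i, j],
        }
    )
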