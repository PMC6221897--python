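"""Graph statistics on single-trial PLV networks.

Strength
    Nodal strength of node k is the *mean* edge weight incident to k,
    s_k = (1/(N-1)) * sum_{j != k} w_kj, so it stays in [0, 1] for PLV
    weights; global network strength is the mean of nodal strengths, which
    equals the mean over all N(N-1)/2 distinct edges. (A ``convention="sum"``
    switch gives the plain edge-weight sum instead; the two differ by the
    constant factor N-1.)

Communicability
    Qexp = expm(D^{-1/2} A D^{-1/2}) with D = diag of row sums — the
    degree-normalized weighted communicability of Crofts & Higham. Entry
    (i, j) sums the walks between i and j down-weighted by 1/length!, so it
    captures multi-path information flow; the normalization removes overall
    scale, making Qexp invariant to A -> cA for c > 0. Nodal communicability
    averages row entries excluding the diagonal. A ``normalized=False``
    switch computes the raw expm(A) instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .connectivity import ConnectivityTensor

logger = logging.getLogger(__name__)

EPS_FLOOR = 1e-12


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-9):
        raise ValueError("adjacency must be symmetric")
    if (adj < 0).any():
        raise ValueError("edge weights must be non-negative")
    return adj


def nodal_strength(adj: np.ndarray, convention: str = "mean") -> np.ndarray:
    """Per-node strength of one symmetric zero-diagonal adjacency matrix."""
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    s = adj.sum(axis=1) - np.diag(adj)
    if convention == "mean":
        return s / max(n - 1, 1)
    if convention == "sum":
        return s
    raise ValueError(f"unknown strength convention {convention!r}")


def global_strength(adj: np.ndarray, convention: str = "mean") -> float:
    """Mean (or summed) edge weight of the whole network.

    Under the mean convention this equals both the mean of nodal strengths
    and the mean over the N(N-1)/2 distinct edges.
    """
    return float(nodal_strength(adj, convention).mean())


def communicability_matrix(adj: np.ndarray, normalized: bool = True, eps: float = EPS_FLOOR) -> np.ndarray:
    """Weighted communicability matrix Qexp of one network.

    Isolated nodes (zero strength) get their normalization floored at
    ``eps`` with a warning, leaving them near-disconnected in Qexp.
    """
    adj = _check_adjacency(adj)
    if not normalized:
        return expm(adj)
    d = adj.sum(axis=1)
    isolated = d <= 0
    if isolated.any():
        logger.warning("%d isolated node(s); normalization floored at %g", int(isolated.sum()), eps)
        d = np.where(isolated, eps, d)
    dinv = 1.0 / np.sqrt(d)
    return expm(adj * np.outer(dinv, dinv))


def nodal_communicability(qexp: np.ndarray) -> np.ndarray:
    """Mean off-diagonal communicability per node (row mean sans diagonal)."""
    qexp = np.asarray(qexp, dtype=float)
    n = qexp.shape[0]
    return (qexp.sum(axis=1) - np.diag(qexp)) / max(n - 1, 1)


@dataclass
class NetworkFeatures:
    """Strength and communicability features per trial and bin."""

    global_strength: np.ndarray   # (trial, bin)
    nodal_strength: np.ndarray    # (trial, bin, channel)
    nodal_qexp: np.ndarray        # (trial, bin, channel)
    channel_labels: list[str]
    bin_edges: tuple[tuple[float, float], ...]


def network_features(conn: ConnectivityTensor, convention: str = "mean", normalized: bool = True) -> NetworkFeatures:
    """Strength and communicability of every trial x bin PLV network."""
    n_tr, n_bin, n_ch, _ = conn.plv.shape
    nodal = np.empty((n_tr, n_bin, n_ch))
    qexp = np.empty((n_tr, n_bin, n_ch))
    for r in range(n_tr):
        for b in range(n_bin):
            A = conn.plv[r, b]
            nodal[r, b] = nodal_strength(A, convention)
            qexp[r, b] = nodal_communicability(communicability_matrix(A, normalized))
    return NetworkFeatures(
        global_strength=nodal.mean(axis=2),
        nodal_strength=nodal,
        nodal_qexp=qexp,
        channel_labels=list(conn.channel_labels),
        bin_edges=conn.bin_edges,
    )


def save_network_features(feats: NetworkFeatures, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("global_strength", data=feats.global_strength)
        f.create_dataset("nodal_strength", data=feats.nodal_strength)
        f.create_dataset("nodal_qexp", data=feats.nodal_qexp)
        f.create_dataset("bin_edges", data=np.asarray(feats.bin_edges))
        f.attrs["channel_labels"] = [str(c) for c in feats.channel_labels]


def load_network_features(path) -> NetworkFeatures:
    with h5py.File(path, "r") as f:
        return NetworkFeatures(
            global_strength=f["global_strength"][()],
            nodal_strength=f["nodal_strength"][()],
            nodal_qexp=f["nodal_qexp"][()],
            bin_edges=tuple(tuple(b) for b in f["bin_edges"][()]),
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
        )


def nodal_table(feats: NetworkFeatures, bin_index: int) -> pd.DataFrame:
    """Per-channel mean strength and communicability in one bin."""
    return pd.DataFrame(
        {
            "channel_label": feats.channel_labels,
            "strength": feats.nodal_strength[:, bin_index].mean(axis=0),
            "qexp": feats.nodal_qexp[:, bin_index].mean(axis=0),
        }
    )
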