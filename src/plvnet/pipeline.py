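"""End-to-end orchestration: session -> epochs -> PLV networks -> statistics
-> decoder, with a structured report bundle.

A :class:`RunConfig` describes one analysis run: the input session (an EDF +
event-table pair, or a simulator configuration), the frequency bands, epoch
window, analysis bins, statistics options and decoder options. :func:`run`
executes the stages in order and returns a plain-dict bundle;
:func:`report` serializes the bundle as CSV/JSON tables plus a text summary.

When an output directory is given, the two expensive stages (epoching and
feature extraction) are cached to HDF5 keyed by a hash of the part of the
configuration they depend on, so re-running with only downstream options
changed (e.g. a different number of decoder permutations) reuses the cached
upstream results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import connectivity as conn_mod
from . import io as io_mod
from . import netmetrics, spectral, stats
from .decoder import DecoderResult, FeatureMatrix, permutation_test
from .simulate import SimConfig, simulate_session

logger = logging.getLogger(__name__)

PRECUE_BIN = (-500.0, 0.0)


@dataclass
class RunConfig:
    """Full configuration of one analysis run.

    Exactly one of ``sim`` (simulator config) and ``edf_path``/``events_path``
    must be provided.
    """

    sim: SimConfig | None = None
    edf_path: str | None = None
    events_path: str | None = None

    gamma_band: tuple[float, float] = (70.0, 100.0)
    low_band: tuple[float, float] = (3.0, 12.0)
    window: tuple[float, float] = (-0.5, 1.5)
    buffer: float = 0.5
    delay_filter: float = 1500.0
    bins: tuple[tuple[float, float], ...] = conn_mod.DEFAULT_BINS

    alpha: float = 0.05
    rt_contrast_sided: str = "less"        # fast RTs rank below slow RTs
    strength_contrast_sided: str = "two"

    decoder_enabled: bool = True
    decoder_folds: int = 10
    decoder_n_perm: int = 1000
    decoder_null: str = "generated"
    qexp_channel: str = "auto"             # label, or "auto" = max |t| fast-slow

    seed: int = 0

    def __post_init__(self) -> None:
        has_sim = self.sim is not None
        has_files = self.edf_path is not None or self.events_path is not None
        if has_sim == has_files:
            raise ValueError("provide exactly one of simulator config or input paths")
        bins = sorted(self.bins)
        for (a0, a1), (b0, b1) in zip(bins, bins[1:]):
            if b0 < a1:
                raise ValueError("analysis bins must be non-overlapping and ordered")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            for key in ("delay_options", "gamma_band", "low_band", "coupling_range"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        for key in ("gamma_band", "low_band", "window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "bins" in d and d["bins"] is not None:
            d["bins"] = tuple(tuple(b) for b in d["bins"])
        return cls(**d)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _cache_valid(path: Path, key: str) -> bool:
    if not path.exists():
        return False
    try:
        with h5py.File(path, "r") as f:
            return f.attrs.get("config_hash") == key
    except OSError:
        return False


def _stamp(path: Path, key: str) -> None:
    with h5py.File(path, "a") as f:
        f.attrs["config_hash"] = key


def _precue_index(bins) -> int:
    for i, b in enumerate(bins):
        if tuple(b) == PRECUE_BIN:
            return i
    return 0


def run(
    config: RunConfig,
    output_dir: str | None = None,
    use_cache: bool = True,
    stop_after: str | None = None,
) -> dict:
    """Execute the full analysis and return the report bundle.

    The bundle is a dict with keys ``config``, ``partition``,
    ``rt_contrast``, ``binwise_strength``, ``nodal_precue`` (per-feature
    tables), ``early_late``, ``correlations``, ``decoder`` (or None) and
    ``log`` (per-stage counts). ``stop_after`` in {"epochs", "features"}
    halts after that stage and returns a partial bundle.
    """
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    log: dict = {}

    # --- stage: epochs ---------------------------------------------------
    epoch_key = _hash(
        {k: cfg[k] for k in ("sim", "edf_path", "events_path", "window", "buffer", "delay_filter", "seed")}
    )
    epochs_file = out / "epochs.h5" if out is not None else None
    if epochs_file is not None and use_cache and _cache_valid(epochs_file, epoch_key):
        logger.info("stage epochs: cache hit (%s)", epoch_key)
        epochs = io_mod.load_epochs(epochs_file)
        log["epochs"] = "cached"
    else:
        if config.sim is not None:
            recording, events, _truth = simulate_session(config.sim)
        else:
            recording = io_mod.read_edf(config.edf_path)
            events = io_mod.read_events(config.events_path)
        epochs = io_mod.epoch(
            recording, events, window=config.window,
            delay_filter=config.delay_filter, buffer=config.buffer,
        )
        if epochs_file is not None:
            io_mod.save_epochs(epochs, epochs_file)
            _stamp(epochs_file, epoch_key)
        log["epochs"] = f"{epochs.n_trials} trials retained"
    logger.info("analyzing %d trials x %d channels", epochs.n_trials, epochs.n_channels)
    if stop_after == "epochs":
        return {"config": cfg, "config_hash": _hash(cfg),
                "n_trials_analyzed": epochs.n_trials, "epochs": epochs, "log": log}

    # --- stage: features -------------------------------------------------
    feat_key = _hash([epoch_key, cfg["gamma_band"], cfg["low_band"], cfg["bins"]])
    plv_file = out / "plv.h5" if out is not None else None
    net_file = out / "network_features.h5" if out is not None else None
    gamma = spectral.BandConfig("high_gamma", *config.gamma_band)
    low = spectral.BandConfig("low", *config.low_band)
    if (
        plv_file is not None and use_cache
        and _cache_valid(plv_file, feat_key) and _cache_valid(net_file, feat_key)
    ):
        logger.info("stage features: cache hit (%s)", feat_key)
        conn = conn_mod.load_connectivity(plv_file)
        net = netmetrics.load_network_features(net_file)
        log["features"] = "cached"
    else:
        phases = spectral.analytic_phase(spectral.bandpass(epochs, gamma), gamma)
        conn = conn_mod.single_trial_plv(phases, config.bins)
        net = netmetrics.network_features(conn)
        if plv_file is not None:
            conn_mod.save_connectivity(conn, plv_file)
            _stamp(plv_file, feat_key)
            netmetrics.save_network_features(net, net_file)
            _stamp(net_file, feat_key)
        log["features"] = "computed"
    if stop_after == "features":
        return {"config": cfg, "config_hash": _hash(cfg),
                "n_trials_analyzed": epochs.n_trials, "connectivity": conn,
                "network_features": net, "log": log}
    spec = spectral.spectral_features(epochs, config.bins, gamma, low)

    # --- stage: statistics ----------------------------------------------
    labels = stats.partition_terciles(epochs.rts)
    fast, slow = labels.mask("fast"), labels.mask("slow")
    early, late = labels.mask("early"), labels.mask("late")
    pre = _precue_index(config.bins)
    threshold = stats.bonferroni(config.alpha, len(config.bins))

    rt_contrast = stats.rank_sum(epochs.rts[fast], epochs.rts[slow], config.rt_contrast_sided)

    binwise = []
    for b, edges in enumerate(config.bins):
        r = stats.rank_sum(
            net.global_strength[fast, b], net.global_strength[slow, b],
            config.strength_contrast_sided,
        )
        binwise.append(
            {
                "bin_start_ms": edges[0], "bin_end_ms": edges[1],
                "z": r.statistic, "p": r.p_value,
                "corrected_threshold": threshold,
                "significant": r.p_value < threshold,
            }
        )
    binwise = pd.DataFrame(binwise)

    nodal_precue = {
        "strength": stats.nodal_contrast_t(net.nodal_strength[:, pre], fast, slow, net.channel_labels),
        "hfa": stats.nodal_contrast_t(spec["hfa_z"][:, pre], fast, slow, net.channel_labels),
        "tilt": stats.nodal_contrast_t(spec["tilt"][:, pre], fast, slow, net.channel_labels),
        "qexp": stats.nodal_contrast_t(net.nodal_qexp[:, pre], fast, slow, net.channel_labels),
    }
    early_late = stats.nodal_contrast_t(net.nodal_strength[:, pre], late, early, net.channel_labels)

    if config.qexp_channel == "auto":
        qexp_ch = nodal_precue["qexp"].max_channel
    else:
        qexp_ch = net.channel_labels.index(config.qexp_channel)
    correlations = pd.DataFrame(
        [
            {"feature": "precue_global_strength",
             **_corr_row(net.global_strength[:, pre], epochs.rts)},
            {"feature": f"precue_qexp[{net.channel_labels[qexp_ch]}]",
             **_corr_row(net.nodal_qexp[:, pre, qexp_ch], epochs.rts)},
        ]
    )

    # --- stage: decoder --------------------------------------------------
    decoder_result: DecoderResult | None = None
    if config.decoder_enabled:
        sel = fast | slow
        fm = FeatureMatrix(
            X=np.column_stack(
                [net.global_strength[sel, pre], net.nodal_qexp[sel, pre, qexp_ch]]
            ),
            y=fast[sel].astype(int),
            feature_names=[
                "precue_global_strength",
                f"precue_qexp[{net.channel_labels[qexp_ch]}]",
            ],
        )
        decoder_result = permutation_test(
            fm, k=config.decoder_folds, n_perm=config.decoder_n_perm,
            seed=config.seed, null=config.decoder_null,
        )
        log["decoder"] = f"AUC={decoder_result.auc:.3f} p={decoder_result.p_value:.4g}"
    else:
        log["decoder"] = "disabled"

    return {
        "config": cfg,
        "config_hash": _hash(cfg),
        "n_trials_analyzed": epochs.n_trials,
        "partition": labels,
        "rt_contrast": rt_contrast,
        "binwise_strength": binwise,
        "nodal_precue": nodal_precue,
        "early_late": early_late,
        "correlations": correlations,
        "qexp_channel": net.channel_labels[qexp_ch],
        "decoder": decoder_result,
        "log": log,
    }


def _corr_row(feature, rts) -> dict:
    r = stats.correlate_rt(feature, rts)
    return {"r": r.statistic, "p": r.p_value, "n": len(rts)}


def report(bundle: dict, path) -> list[str]:
    """Write the bundle as CSV/JSON tables plus a plain-text summary.

    Returns the list of files written.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        f = path / name
        df.to_csv(f, index=False)
        written.append(str(f))

    _write_csv(bundle["binwise_strength"], "binwise_strength_tests.csv")
    for feat, contrast in bundle["nodal_precue"].items():
        _write_csv(contrast.table, f"nodal_precue_{feat}.csv")
    _write_csv(bundle["early_late"].table, "early_late_strength.csv")
    _write_csv(bundle["correlations"], "correlations.csv")

    cfg_file = path / "config_echo.json"
    with open(cfg_file, "w") as fh:
        json.dump(
            {"config": bundle["config"], "config_hash": bundle["config_hash"],
             "log": bundle["log"]},
            fh, indent=2, default=str,
        )
    written.append(str(cfg_file))

    dec = bundle["decoder"]
    if dec is not None:
        dec.to_json(path / "decoder.json")
        pd.DataFrame({"null_auc": dec.null_aucs}).to_csv(path / "decoder_null_aucs.csv", index=False)
        written += [str(path / "decoder.json"), str(path / "decoder_null_aucs.csv")]

    rt = bundle["rt_contrast"]
    lines = [
        f"config hash: {bundle['config_hash']}",
        f"trials analyzed: {bundle['n_trials_analyzed']}",
        f"fast/slow RT contrast: rank-sum z = {rt.statistic:.2f}, "
        f"{rt.sidedness}-sided p = {rt.p_value:.3g}",
        "bin-wise global strength fast-vs-slow rank-sum "
        f"({len(bundle['binwise_strength'])} bins, Bonferroni threshold "
        f"{bundle['binwise_strength']['corrected_threshold'].iloc[0]:.4g}):",
    ]
    for row in bundle["binwise_strength"].itertuples(index=False):
        flag = "*" if row.significant else " "
        lines.append(
            f"  [{row.bin_start_ms:+7.0f}, {row.bin_end_ms:+7.0f}) ms: "
            f"z = {row.z:+.2f}, p = {row.p:.3g} {flag}"
        )
    for feat, contrast in bundle["nodal_precue"].items():
        row = contrast.table.iloc[contrast.max_channel]
        lines.append(
            f"pre-cue nodal {feat} fast-vs-slow, max-|t| channel {row['channel']}: "
            f"t({row['df']:.0f}) = {row['t']:.2f}, p = {row['p']:.3g}"
        )
    row = bundle["early_late"].table.iloc[bundle["early_late"].max_channel]
    lines.append(
        f"early-vs-late control, max-|t| channel {row['channel']}: "
        f"t({row['df']:.0f}) = {row['t']:.2f}, p = {row['p']:.3g}"
    )
    for c in bundle["correlations"].itertuples(index=False):
        lines.append(f"single-trial {c.feature} vs RT: r = {c.r:.2f}, p = {c.p:.3g} (n = {c.n})")
    if dec is not None:
        lines.append(
            f"decoder ({', '.join(dec.feature_names)}): AUC = {dec.auc:.2f}, "
            f"permutation p = {dec.p_value:.3g} ({dec.n_perm} draws, {dec.folds}-fold)"
        )
    else:
        lines.append("decoder: disabled")
    summary = path / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(str(summary))
    return written
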