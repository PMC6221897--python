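"""Build single-trial PLV networks and summarize them with graph metrics.

For each trial and 500-ms bin, the phase-locking value between every pair of
channels forms a weighted adjacency matrix; nodal/global strength and
communicability condense it into per-trial features. Because the simulator
couples channels only in the pre-cue window as a function of the latent
per-trial kappa, pre-cue strength should track kappa while delay-bin
strength should not.
"""

import numpy as np

import plvnet
from plvnet.spectral import GAMMA

cfg = plvnet.SimConfig(n_channels=12, n_trials=50, sampling_rate=512.0,
                       delay_options=(1500.0,), seed=2)
recording, events, truth = plvnet.simulate_session(cfg)
epochs = plvnet.epoch(recording, events)

phases = plvnet.analytic_phase(plvnet.bandpass(epochs, GAMMA), GAMMA)
conn = plvnet.single_trial_plv(phases)  # four contiguous 500-ms bins
net = plvnet.network_features(conn)

print(f"PLV tensor: {conn.plv.shape} (trial, bin, channel, channel)")
for b, edges in enumerate(conn.bin_edges):
    r = np.corrcoef(net.global_strength[:, b], truth.kappa)[0, 1]
    print(f"bin [{edges[0]:+7.0f}, {edges[1]:+7.0f}) ms: "
          f"mean strength {net.global_strength[:, b].mean():.3f}, "
          f"corr with true coupling r = {r:+.2f}")
print("Only the pre-cue bin tracks the injected coupling; the delay bins are")
print("decoupled from it by construction, mirroring a pre-stimulus network state")
print("that predicts upcoming behaviour.")
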