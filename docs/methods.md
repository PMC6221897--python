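# Methods

This note documents the models, conventions and numerical choices behind
`plvnet`, the assumptions of its synthetic-session generator, and what the
test suite does and does not establish about real recordings.

## Signal model and conventions

Times are in seconds with the cue at t = 0; all sample bins are half-open
[start, end), so a (−0.5, 1.5) s window at 1000 Hz holds exactly 2000
samples and neighbouring bins never share a sample. Epochs carry a
configurable buffer (default 0.5 s per side) that absorbs filter edge
artifacts and is trimmed immediately after phase/amplitude extraction.
Trials whose keypress precedes the go signal, or whose padded window falls
outside the recording, are excluded with a logged warning before any
analysis.

## Filtering and phase extraction

Band-pass filtering uses a Hamming windowed-sinc FIR applied forward and
backward (zero group delay — any phase distortion here would bias the PLV
directly). The transition width per edge is max(25 % of the edge frequency,
2 Hz), capped at the edge itself; the 2-Hz floor keeps the low-band
(3–12 Hz) kernel short enough to fit task epochs — a bare 25 % rule would
give a 0.75-Hz transition and a ~2 s kernel, longer than the epoch.
Kernel length follows the Hamming approximation 3.3·fs/Δf, forced odd. The
forward-backward pass is implemented as a single FFT (overlap-add)
convolution with the symmetric kernel conv(b, b), with odd-reflection
padding; this is algebraically the forward-backward response at
O(N log N) cost. Stopband attenuation is ~53 dB per pass (~106 dB
combined); passband ripple is negligible.

Instantaneous phase is the argument of the analytic signal
(`scipy.signal.hilbert`) of the band-limited data. Band power in a bin is
mean(|analytic|²)/2, which equals the mean-square signal power of a
narrowband signal (a unit sinusoid gives 0.5). HFA and low-band power are
z-scored per (channel, bin) across trials with the sample (n−1) standard
deviation; spectral tilt is their elementwise difference. Power is not
log-transformed before z-scoring (a config switch could be added; the
across-trials z already removes per-channel scale).

## PLV networks

Single-trial PLV in bin b: PLV_ij = |(1/T) Σ_{t∈b} exp(i(φ_i(t) −
φ_j(t)))|. The estimator averages over time samples within one trial — the
only reading compatible with per-trial features. Bins require ≥ 32 samples.
The adjacency diagonal is set to 0 (so strength sums need no self-edge
correction) and symmetry is enforced bitwise by averaging the matrix with
its transpose (complex matrix products are not bitwise symmetric). The
finite-sample chance level for T independent phase samples is
E|mean of T unit phasors| ≈ √π/(2√T); after narrowband filtering the
effective number of independent phase samples in a bin is far below the
sample count (the filter's ~30 Hz bandwidth gives a phase decorrelation
time of ~30 ms), so empirical "no-coupling" PLV floors sit well above the
per-sample chance level. Sliding-bin edges are configurable (width, step);
the default is the four contiguous 500-ms analysis bins from −500 to
+1500 ms.

## Graph statistics

Nodal strength uses the mean-edge convention s_k = (1/(N−1)) Σ_{j≠k} w_kj,
keeping it in [0, 1] for PLV weights; global strength is the mean over
nodes, which equals the mean over the N(N−1)/2 distinct edges. The two
common textbook phrasings (mean per node vs mean per edge) then agree
exactly, and a `convention="sum"` switch exposes the plain sum (factor
N−1). Communicability uses the degree-normalized form
Qexp = expm(D^{−1/2} A D^{−1/2}), the standard weighted-network choice;
it is invariant to uniform edge scaling A → cA, so it captures *relative*
network organization, not overall coupling level. `normalized=False` gives
plain expm(A). Isolated nodes get an epsilon floor (1e-12) on their row sum
with a warning. The matrix exponential is `scipy.linalg.expm`; tests verify
it against a 30-term power series to 1e-10.

## Statistics

Tercile partition: trials ranked by RT ascending; the first and last
floor(n/3) form the fast and slow groups (57 trials → 19 + 19). RT ties
straddling a boundary are resolved chronologically (earlier trial takes the
lower-rank class) and logged; the chronological early/late partition uses
the same group sizes. The rank-sum test uses midranks, tie-corrected
variance and a 0.5 continuity correction; its exact level at group sizes
10/10 is 0.0433 rather than 0.05 (discreteness plus the conservative
continuity correction) — intrinsic to the normal-approximation test, not an
implementation artifact. Per-channel contrasts use Welch's t with
Welch–Satterthwaite degrees of freedom; with two groups of 19 this yields
df ≤ 36 depending on the variance ratio, reported transparently. Pearson
correlations use the t-transform p-value. The Bonferroni threshold is
applied over the four time bins (α/4 = 0.0125); no correction is applied
across channels in the per-node tables by default — the tables report raw
p-values and the analysis threshold, and readers of the per-channel tables
should treat the max-|t| channel as selected post hoc.

## Decoder

Stratified k-fold (default 10) with per-fold standardization fit on the
training fold only; linear-kernel SVM with C = 1 (two features make a
nonlinear kernel unmotivated; C is not tuned); decision values pooled
across folds into a single AUC (more stable than per-fold AUCs at n ≈ 38).
The null distribution regenerates labels as fair Bernoulli(0.5) per trial —
labels "randomly generated", not permuted — with a `null="permuted"` option
preserving class balance; labelings too imbalanced to stratify are redrawn
and counted. The p-value is add-one: p = (1 + #{null ≥ observed})/(1 +
n_perm), so p ≥ 1/(n_perm + 1) always.

## Synthetic sessions

Each channel sums three components (microvolts): 1/f^β Gaussian background
(FFT-shaped; β defaults to 2, typical of field-potential spectra over the
gamma range), one low-frequency sinusoid at a per-channel frequency in
3–12 Hz, and a high-gamma oscillation cos(φ_c(t) + η_ch(t)) around a
session-wide common oscillator φ_c at the band centre (85 Hz). The jitter
η is drawn per channel as von Mises angles on a 50-ms block grid and
interpolated through unit phasors between blocks; per-sample independent
jitter would be averaged away by the band-pass kernel, compressing the
κ → PLV map (strength–κ correlation ≈ 0.4 instead of ≈ 0.96). The
concentration is κ·κ_max with κ_max = 4 by default: at the spread the
block model produces, this maps κ ∈ [0, 1] onto measured pre-cue PLV
≈ 0.3 → 0.85 nearly linearly, whereas large concentrations saturate the
map. κ_max = ∞ is supported and yields PLV ≈ 1 (zero jitter).

Coupling windows: the trial's κ_i governs the 500-ms pre-cue window; the
delay window gets an independent uniform draw; all other samples are
uncoupled (uniform jitter). Coupled windows are padded outward by 0.2 s so
the filter kernel does not smear uncoupled flanking signal into the
analysis bins; without the pad, zero-jitter trials plateau at PLV ≈ 0.97
instead of > 0.99. Gamma amplitude is log-normal per trial × channel
(σ = 0.3, unit mean) with ~100-ms ramps between levels (a hard step would
inject a broadband transient at the bin edge); amplitude is independent of
κ, so power-based and phase-based features are dissociable by
construction. Reaction times follow RT = r0 − r1·κ + ε, ε ~ N(0, σ_RT),
floored at 100 ms; defaults r0 = 350 ms, r1 = 100 ms, σ_RT = 50 ms give a
true κ–RT correlation of −0.5 (r1 = 2σ_RT with κ uniform). Defaults
n_channels = 122 and delays 500/1500 ms with equal probability emulate a
session of roughly a hundred contacts where about half the trials carry
the analyzed 1500-ms delay; n_trials = 114 leaves ~57 analyzable trials.
RTs are stored as the exact float the event table reproduces
((keypress − go)·1000), so file round trips recover them bit-exactly.

What the generator does **not** emulate: node-heterogeneous coupling (all
channels share one κ per window, so nodal communicability carries no
injected behavioural signal — in synthetic sessions the max-|t| Qexp
channel is a post-hoc selection from a homogeneous network and its RT
correlation fluctuates around selection-level noise, with arbitrary sign),
biophysical dynamics, line noise, artifacts, non-stationary drift, or
epileptiform activity. Passing tests therefore establish estimator
correctness and sensitivity/specificity under a controlled coupling model,
not robustness to real-data pathologies.

A mild consequence of the 1/f² background's long-range autocorrelation is
weak dependence between trials, which makes delay-bin contrasts slightly
conservative in large null batteries; the pre-cue designated tests
calibrate within the expected binomial band.

## Pipeline, caching, determinism

`run()` executes epoching → PLV/graph features → spectral features →
statistics → decoder from one `RunConfig`; exactly one input source
(simulator config, or EDF + event CSV) must be given. With an output
directory, epochs and network features are cached to HDF5 stamped with a
hash of the configuration slice they depend on; downstream-only changes
(statistics or decoder options) reuse the cache. All randomness flows from
explicit seeds; reruns are bit-identical. EDF files are written by a
minimal built-in standard-EDF (16-bit) writer — one-second records,
per-channel physical calibration — and read back through MNE, which doubles
as an independent check on the writer.

## Test-suite problem sizes

The statistical-calibration battery uses 500 null sessions of 8 channels ×
30 trials (all at the analyzed delay) at 256 Hz, evaluating one designated
rank-sum (pre-cue global strength) and one designated Welch test (channel
0) per session so the 500 draws are independent, as the binomial band
assumes. Effect-recovery uses 20 sessions of 16 channels × 60 trials with
the default (true r ≈ −0.5) coupling–RT link and a 200-draw permutation
decoder; the acceptance script scales up to 122 channels and 1000
permutation draws. Decoder null-calibration in the unit tests uses 24
trials, 3 folds and 100 draws per run across 200 runs.
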