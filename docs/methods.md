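# Methods

This note documents the models and procedures the package implements, the
parameters that matter, and what the synthetic validation does and does not
establish.

## Signal model and the LEiDA front end

Epochs are real matrices (channels × samples) at a sampling rate of 500 Hz
by default. Band-limiting uses a zero-phase 4th-order Butterworth band-pass
(default 1–40 Hz, forward–backward `sosfiltfilt`), which removes DC and
leaves no phase distortion; the 1 Hz low edge implies a filter transient of
roughly 1–2 s at each epoch edge. Instantaneous phase θ(n, t) and envelope
A(n, t) come from the analytic signal (Hilbert transform) per channel; a
constant channel has no phase and is rejected by name.

The dynamic phase-locking tensor is the per-sample cosine of pairwise phase
differences, `dPL(n, p, t) = cos(θ(n, t) − θ(p, t))` — no windowing and no
temporal smoothing, so one slice per retained sample. A decimation factor
(default 25 in the drivers, i.e. one slice per 50 ms) is exposed purely for
speed; it subsamples slices, never averages them. One carrier period is
discarded at each epoch edge before the tensor is formed, clearing Hilbert
and filter edge artifacts (standard analytic-signal practice).

Each slice is symmetric with unit diagonal; its leading eigenvector (the
unit eigenvector of the largest-magnitude eigenvalue, via a batched
symmetric eigendecomposition) summarises the dominant phase-alignment
pattern. Eigenvectors are sign-ambiguous, so a deterministic convention is
applied: flip so the majority of elements are negative; exact ties force
the first element non-positive. The convention is idempotent, and the
whole chain is bit-reproducible.

## PL states and their statistics

Leading eigenvectors from all epochs are pooled in deterministic (subject,
condition, time) order and clustered with k-means — Euclidean distance on
unit-norm vectors, which is monotonically related to cosine distance;
k-means++ seeding, best of `n_init = 20` restarts by inertia, fixed seed.
Both conditions are pooled together: states are a shared repertoire and
conditions may differ only in how they occupy it, which is what makes the
occupancy contrast meaningful. States are renumbered 1..k by descending
total occupancy so identities are stable across reruns. k = 8 is the
configured headline solution; `scan_k` reports inertia and silhouette for
alternatives but performs no automatic selection.

Per subject × condition: occupancy is the fraction of time points assigned
to each state; dwell time is the mean length of maximal runs of identical
labels (runs truncated at epoch boundaries), reported in steps and,
when a step duration is supplied, seconds; transition matrices are
empirical next-step frequencies within epochs, rows of unvisited states
undefined (NaN).

## Inference

The per-state condition contrast uses the Welch (unequal-variance) t
statistic, positive when condition B exceeds A. Its null distribution is
built by permutation (default 10,000 iterations). Because each subject
contributes both conditions, the default scheme flips each subject's A/B
pair with probability 1/2 per iteration — the exchangeability matching the
within-subject design; an unpaired full-reshuffle mode is available to
match a literal two-independent-samples reading. Two-sided p-values use
the finite-permutation estimator `p = (1 + #{|t0| ≥ |t|}) / (n_perm + 1)`,
never exactly zero and slightly conservative. Across states, p-values are
Benjamini–Hochberg adjusted (via statsmodels); the graph-metric family
uses Bonferroni (`min(1, p·m)`), matching its more conservative
convention. Parametric Welch p-values appear only in the graph-metric
comparison, where the permutation machinery would be overkill for the
record counts involved.

## Connectivity graphs

"Connectivity" is operationalised as the time-averaged |dPL| per channel
pair — a phase-locking-value-style synchrony index in [0, 1] — rather than
spectral magnitude-squared coherence, because the retained quantity is
explicitly the robust phase-locking value. Thresholding is first-class in
two modes: absolute (keep pairs strictly above a cutoff, default 0.2) and
proportional (keep the ⌈q·N(N−1)/2⌉ strongest pairs, default q = 0.2, ties
broken by ascending channel-index pair order). Metrics are computed on the
binarized topology (weights kept as edge attributes): binary local
clustering coefficient (degree < 2 scores 0), characteristic path length
as mean shortest-path hop count — undefined (NaN) on disconnected graphs,
which is a value, not an error — degree statistics, and greedy
(Clauset–Newman–Moore) modularity with deterministic tie-breaking.
Note that on the synthetic generator's dense phase structure an absolute
0.2 cutoff typically yields complete graphs; the proportional mode is the
informative one there.

## Classifier

The three feature kinds are built per retained time point: raw channel
values (F = N), row-major flattened dPL slices (F = N²), and leading
eigenvectors (F = N). One sample is one time point, grouped by subject —
the only reading of "subjects × samples" inputs that yields enough
training data. The network is a compact NumPy implementation (forward,
backprop, Adam 1e-3) of a small 1D-CNN: Conv1D(64 filters, kernel 3, ReLU)
→ MaxPool(2) → Dropout(0.5, inverted scaling) → Flatten → Dense(100, ReLU)
→ Dense(1, sigmoid), binary cross-entropy, batch 10, ≤10 epochs, 20%
validation split, early stopping after 5 epochs without validation-accuracy
improvement, accuracy at threshold 0.5. Standardisation statistics come
from the training split only (asserted by test). Two split modes are
reported: the literal random stratified 80/20 of samples, and a
subject-disjoint (group-aware) split — per-time-point samples from one
subject on both sides inflate accuracy, so the group-aware mode is the
honest generalisation estimate and the random mode reproduces the
protocol whose near-perfect accuracies the benchmark emulates.

## Synthetic-data generator

The generator emulates the two-condition study design: per subject and
condition one epoch of N = 64 channels (10–20-style labels) at 500 Hz with
a 10 Hz carrier, defaults 47 subjects and 20 s per condition. Each planted
state partitions channels into three unequal rotating cyclic communities
(~45/33/22%; two communities below 6 channels); communities share a phase
offset, offsets equally spaced on [0, π). Unequal sizes keep the expected
dPL slice's leading eigenvalue non-degenerate, and the graded three-offset
profile separates states robustly — with two equal communities at offset
π/2 the two block eigenvalues tie and V1 flips randomly between blocks.

State dynamics are a hidden Markov chain at a coarse 25-sample state step
(50 ms), default self-stay 0.9, so states persist ~0.5 s ≈ 5 carrier
cycles — eigenvector dynamics need state epochs long relative to the
filter + Hilbert smearing (~60 ms around each switch). Condition B
multiplies the designated state's self-transition by `occupancy_boost`
(default 1.05, ≈ +0.08 stationary occupancy — a moderate single-state
effect; the occupancy response to this knob is steeply nonlinear near a
self-stay of 1) and renormalises the row; initial states are drawn from
each condition's stationary distribution. Noise: von Mises phase jitter
(κ = 20) per channel and sample, plus additive Gaussian amplitude noise
(sd = 0.3) — chosen so planted-state recovery is achievable but not
trivial. Per-epoch random streams derive from (seed, subject, condition),
so datasets are bit-reproducible and epochs independent of generation
order.

The `separable_benchmark_config` variant instantiates the
condition-separable regime for the classifier: rare-but-quickly-entered
designated state (baseline entry 0.02/step), boost 9.998 making it
near-absorbing in B (stationary occupancy ~0.99 vs ~0.02 in A), κ = 50,
amplitude sd = 0.2, 16 subjects × 6 000 samples. The per-sample Bayes
ceiling of condition classification there is ~0.98.

What the generator does **not** emulate: 1/f background spectra, alpha
peaks, artifacts (blinks, muscle), volume conduction, inter-subject
topography differences, or non-stationary amplitudes. Passing tests
therefore establish correctness of the pipeline's computations and
calibration of its inference under the planted model — not performance on
real recordings.

## Numerical and design choices

- Eigen-decomposition: `numpy.linalg.eigh` batched over slices; tests
  cross-check against the general non-symmetric `eig` routine.
- dPL slices are explicitly symmetrised ((M + Mᵀ)/2) and the diagonal set
  to exactly 1 to make the type invariants bitwise.
- k-means empty clusters are handled inside scikit-learn's solver;
  degenerate pools (identical rows) collapse to one occupied state.
- Welch t with both variances zero: 0 for equal means, signed infinity
  otherwise (the infinity is the flag).
- Dwell and transitions never cross epoch boundaries.
- EDF export is a minimal 16-bit writer (single-purpose, record size under
  the 61,440-byte guideline); round trips are exact to the quantization
  step and verified against MNE's independent EDF reader. TSV export uses
  17-significant-digit formatting and round-trip float parsing, so it is
  bit-exact.
- Pipeline runs derive per-stage seeds from a single global seed by stable
  hashing of the stage name; summaries embed a config hash.

## Problem sizes used in the validation suite

The test and driver configurations are scaled to the information they
need: parameter-recovery runs use 12 subjects × 8 channels × 16 s epochs
with 3 planted states; inference calibration uses 500 null datasets
(n_perm = 1000) and a 100-dataset power run; the end-to-end null uses 20
seeded 12-subject runs; the drivers run 16 subjects × 16 channels × 60 s.
The full 47 × 64 emulation is available behind `--full` and via the
library defaults.

## Known limitations

- The permutation test assumes within-subject exchangeability of the A/B
  pair; it does not model session or order effects (none exist in the
  generator).
- Greedy modularity is a heuristic lower bound on the optimal partition;
  tests bound it by exhaustive search only on small graphs.
- The CNN is intentionally small and CPU-bound; it is a faithful
  implementation of the stated architecture, not a tuned classifier.
- Characteristic path length is undefined on disconnected graphs and the
  comparison excludes such records pairwise, reporting the exclusion
  count; with few subjects this can leave a metric untestable (it is then
  skipped and flagged).
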