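# leida-eeg

Dynamic brain-network states from multichannel oscillatory signals:
**Leading Eigenvector Dynamics Analysis (LEiDA)** for EEG-like data, with
occupancy inference, graph-theoretic network comparison, and a small 1D-CNN
condition classifier — exercised end to end on a synthetic two-condition
(social vs non-social cue) study emulation with planted ground truth.

It is written for computational-neuroscience practitioners who want a
tested, reproducible LEiDA pipeline whose every stage can be validated
against known ground truth before it ever touches real recordings.

## The method

Given a band-limited epoch `x(n, t)` of N channels, the Hilbert transform
yields the analytic representation `x(t) = A(t) cos(θ(t))` per channel. At
every time point the **dynamic phase-locking (dPL)** matrix is

    dPL(n, p, t) = cos(θ(n, t) − θ(p, t))

(1 in-phase, 0 orthogonal, −1 anti-phase; an N × N × T tensor). Each slice
is summarised by its **leading eigenvector** `V1(t)` — the unit eigenvector
of the largest-magnitude eigenvalue — which carries the dominant phase-
alignment pattern. Pooled `V1(t)` rows from all subjects and conditions are
clustered with k-means (headline k = 8) into recurrent **PL states**; per
subject and condition the pipeline derives fractional **occupancy**, mean
**dwell time**, and state **transition matrices**.

Inference: per-state occupancy is contrasted between conditions with a
Welch t statistic under a 10,000-iteration permutation scheme (condition
labels flipped within subject by default), with Benjamini–Hochberg FDR
across states. Network structure: time-averaged |dPL| matrices are
thresholded (absolute 0.2, or top-20% proportional) into undirected graphs
compared on clustering coefficient, characteristic path length (NaN when
disconnected), degree, and modularity, Bonferroni-adjusted. Classification:
a compact NumPy 1D-CNN — Conv1D(64, k=3, ReLU) → MaxPool(2) → Dropout(0.5)
→ Flatten → Dense(100, ReLU) → Dense(1, sigmoid) — is trained (Adam, BCE,
≤10 epochs, batch 10, patience-5 early stopping) on three per-time-point
feature kinds: raw channel values, row-flattened dPL slices, and `V1(t)`.

The synthetic generator plants a Markov-switching repertoire of
phase-locking states (phase-aligned channel communities at offsets spaced
on [0, π)) in 64-channel, 500 Hz signals with a 10 Hz carrier inside a
1–40 Hz band; the two conditions share the repertoire and differ only in
the occupancy of one designated state. Every downstream number is therefore
checkable against planted truth.

## Worked example

The numbered drivers under `analysis/` run the study emulation at desk
scale (16 subjects, 16 channels, 60 s per condition, 8 planted states,
state 7 boosted ×1.05 in condition B) and write their tables to `results/`:

```bash
python analysis/01_simulate.py        # generate + write epochs
python analysis/02_phase_states.py    # Hilbert → dPL → V1(t) → k-means (k=8)
python analysis/03_occupancy_stats.py # permutation + FDR per state
python analysis/04_graphs.py          # thresholded graphs + comparison
python analysis/05_classify.py        # 1D-CNN on three feature kinds
```

Output of the first three steps (seed 0):

```
planted occupancy of state 7: A = 0.125, B = 0.217 (boost x1.05)
pooled 38272 eigenvectors of dimension 16
k = 8, inertia = 2614.87
 state   t_obs  p_raw  p_fdr
     1  6.0341 0.0003 0.0024
     2  0.7972 0.4884 0.6511
     ...
states with p_FDR < 0.05: [1]
```

Exactly one PL state separates the conditions after FDR — the cluster
capturing the boosted planted state (renumbered to 1, as states are ordered
by total occupancy). The mild negative t values in other states are the
compensation forced by occupancies summing to 1. The classifier comparison
(`05_classify.py`, condition-separable benchmark, mean ± sd over 3 seeds)
prints:

```
       split        kind         mean_accuracy
random-80/20        dpl_flat     0.9938
random-80/20        eigenvector  0.9934
random-80/20        raw          0.9707
random-80/20        eigenvector (labels shuffled)  0.5073
```

i.e. eigenvector features reach near-perfect accuracy and beat raw signals,
and shuffled labels fall to chance — the qualitative pattern the pipeline
is designed to expose.

A `leida-eeg` CLI (`simulate`, `phase`, `cluster`, `test`, `graph`,
`classify`, `run-all`, `report`) wraps the same stages for ad hoc runs.

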