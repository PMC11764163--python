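#!/usr/bin/env python
"""Hilbert phase -> dPL -> leading eigenvectors -> k-means PL states.

Reads the epochs written by 01_simulate.py, runs the LEiDA front end per
epoch (1-40 Hz band, one carrier period trimmed per edge, one dPL slice
every 25 samples = 50 ms), pools the leading eigenvectors across subjects
and conditions, clusters at the headline k = 8, and writes the state model,
per-subject state metrics, and a k-scan table.
"""

import argparse
import json
from pathlib import Path

from leida_eeg import phase, states, synth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--k", type=int, default=8)
    ap.add_argument("--decimation", type=int, default=25)
    args = ap.parse_args()

    epoch_dir = ROOT / "results" / "epochs"
    cfg = synth.SyntheticConfig.from_json((epoch_dir / "config.json").read_text())
    epochs = synth.read_epochs(epoch_dir)
    print(f"loaded {len(epochs)} epochs ({epochs[0].n_channels} channels)")

    eig_series = []
    for ep in epochs:
        eig, _ = phase.epoch_to_eigenvectors(
            ep, band=(1.0, 40.0), carrier_freq=cfg.carrier_freq,
            decimation=args.decimation,
        )
        eig_series.append(eig)
    pool = states.pool_eigenvectors(eig_series)
    print(f"pooled {pool.vectors.shape[0]} eigenvectors of dimension {pool.vectors.shape[1]}")

    model = states.cluster_eigenvectors(pool, k=args.k, seed=args.seed)
    step_seconds = args.decimation / cfg.sampling_rate
    metrics = states.compute_state_metrics(model, pool, step_seconds=step_seconds)

    out = ROOT / "results"
    (out / "state_model.json").write_text(model.to_json())
    metrics.occupancy.to_csv(out / "state_metrics.tsv", sep="\t", index=False)
    scan = states.scan_k(pool, range(2, min(13, args.k + 5)), n_init=5, seed=args.seed)
    scan.to_csv(out / "k_scan.tsv", sep="\t", index=False)
    meta = {
        "k": args.k,
        "decimation": args.decimation,
        "pooling": "per-subject eigenvectors pooled across subjects and conditions",
        "inertia": model.inertia,
    }
    (out / "states_meta.json").write_text(json.dumps(meta, indent=1))

    occ = metrics.occupancy.groupby("state")["occupancy"].mean()
    print(f"k = {args.k}, inertia = {model.inertia:.2f}")
    print("mean occupancy by state:")
    print(occ.round(3).to_string())


if __name__ == "__main__":
    main()
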