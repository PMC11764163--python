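"""Configured end-to-end runs: synth -> phase -> states -> stats -> graphs -> clf.

A single global seed deterministically derives one sub-seed per stage (via
stable hashing of the stage name), so a run is fully reproducible from its
config alone.  Every stage writes its artifacts into the run directory and
the run closes with a machine-readable ``summary.json`` carrying the config
hash, the seed, and the headline numbers of each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clf, graphs, io, phase, states, stats, synth

log = logging.getLogger("leida_eeg")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    synth: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    band: tuple[float, float] = (1.0, 40.0)
    decimation: int = 25
    k: int = 8
    n_init: int = 20
    n_perm: int = 10_000
    threshold_mode: str = "absolute"
    threshold_value: float = 0.2
    classifier: clf.ClassifierConfig = field(default_factory=clf.ClassifierConfig)
    permutation_scheme: str = "paired"
    run_classifier: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["transition_matrix"] = np.asarray(
            self.synth.transition_matrix
        ).tolist()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; write artifacts and return the summary dict.

    Stage failures abort with the stage name attached so a broken run is
    attributable from the exception alone.
    """
    out = io.ensure_dir(out_dir)
    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    stage = "synth"
    try:
        syn_cfg = dataclasses.replace(config.synth, seed=stage_seed(config.seed, "synth"))
        dataset = synth.generate_dataset(syn_cfg)
        synth.write_epochs(dataset, out / "epochs", format="tsv")
        summary["synth"] = {"n_epochs": len(dataset.epochs)}
        log.info("synth: %d epochs", len(dataset.epochs))

        stage = "phase"
        eig_series, dpl_series = [], []
        for ep in dataset.epochs:
            eig, dpl = phase.epoch_to_eigenvectors(
                ep,
                band=config.band,
                carrier_freq=syn_cfg.carrier_freq,
                decimation=config.decimation,
            )
            eig_series.append(eig)
            dpl_series.append(dpl)
        eig_dir = io.ensure_dir(out / "eigenvectors")
        for eig in eig_series:
            phase.save_eigenvectors(eig, eig_dir / f"{eig.subject_id}_{eig.condition}.npz")
        summary["phase"] = {
            "n_eigenvectors": int(sum(e.vectors.shape[0] for e in eig_series)),
            "decimation": config.decimation,
        }

        stage = "states"
        pool = states.pool_eigenvectors(eig_series)
        model = states.cluster_eigenvectors(
            pool, config.k, n_init=config.n_init, seed=stage_seed(config.seed, "states")
        )
        step_seconds = config.decimation / syn_cfg.sampling_rate
        metrics = states.compute_state_metrics(model, pool, step_seconds=step_seconds)
        (out / "state_model.json").write_text(model.to_json())
        metrics.occupancy.to_csv(out / "state_metrics.tsv", sep="\t", index=False)
        summary["states"] = {"k": model.k, "inertia": model.inertia}

        stage = "stats"
        contrast = stats.contrast_from_metrics(metrics)
        results = stats.permutation_test(
            contrast,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "stats"),
            scheme=config.permutation_scheme,
        )
        rf = stats.results_frame(results)
        rf.to_csv(out / "occupancy_tests.tsv", sep="\t", index=False)
        summary["stats"] = {
            "n_perm": config.n_perm,
            "scheme": config.permutation_scheme,
            "p_raw": {int(r.state): r.p_raw for r in results},
            "p_fdr": {int(r.state): r.p_fdr for r in results},
            "significant_fdr_05": [int(r.state) for r in results if r.p_fdr < 0.05],
        }

        stage = "graphs"
        records = {
            "A": [
                graphs.graph_metrics(
                    d, config.threshold_mode, config.threshold_value,
                    seed=stage_seed(config.seed, "graphs"),
                )
                for d in dpl_series
                if d.condition == "A"
            ],
            "B": [
                graphs.graph_metrics(
                    d, config.threshold_mode, config.threshold_value,
                    seed=stage_seed(config.seed, "graphs"),
                )
                for d in dpl_series
                if d.condition == "B"
            ],
        }
        comparison = graphs.compare_conditions(records["A"], records["B"])
        comparison.to_csv(out / "graph_comparison.tsv", sep="\t", index=False)
        summary["graphs"] = {
            "threshold_mode": config.threshold_mode,
            "threshold_value": config.threshold_value,
            "comparison": comparison.drop(columns=["skipped"]).to_dict("records"),
        }

        if config.run_classifier:
            stage = "clf"
            feats = {
                "raw": clf.build_features(
                    "raw", epochs=dataset.epochs, decimation=config.decimation
                ),
                "dpl_flat": clf.build_features("dpl_flat", dpl_series=dpl_series),
                "eigenvector": clf.build_features("eigenvector", eig_series=eig_series),
            }
            cnn_cfg = dataclasses.replace(
                config.classifier, seed=stage_seed(config.seed, "clf")
            )
            table = clf.compare_feature_sets(feats, cnn_cfg, n_seeds=3)
            table.to_csv(out / "classifier_accuracy.tsv", sep="\t", index=False)
            summary["clf"] = table.to_dict("records")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
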