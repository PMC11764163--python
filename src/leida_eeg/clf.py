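"""1D-CNN condition classifier over three feature kinds.

Discriminates condition A vs B from (i) raw per-time-point channel values,
(ii) row-major flattened dPL slices, or (iii) leading eigenvectors V1(t).
One sample is one retained time point, grouped by subject; the default split
is subject-disjoint so that per-time-point samples of one subject never
appear on both sides.

The network is a compact NumPy implementation of a standard small 1D-CNN:

    Conv1D(64 filters, kernel 3, ReLU) -> MaxPool(2) -> Dropout(0.5)
    -> Flatten -> Dense(100, ReLU) -> Dense(1, sigmoid)

trained with binary cross-entropy and Adam for at most 10 epochs (batch
size 10, 20% validation split) under patience-5 early stopping on
validation accuracy.  The 1D convolution runs along the feature axis for
all three kinds.  Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .phase import DPLSeries, LeadingEigenvectorSeries, SignalEpoch

FEATURE_KINDS = ("raw", "dpl_flat", "eigenvector")


@dataclass
class FeatureSet:
    kind: str
    samples: np.ndarray  # (M, F)
    labels: np.ndarray  # (M,) in {0, 1}
    grouping: np.ndarray  # (M,) subject id per sample

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite feature values")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not (len(self.samples) == len(self.labels) == len(self.grouping)):
            raise ValueError("samples/labels/grouping lengths differ")


@dataclass
class ClassifierConfig:
    conv_filters: int = 64
    kernel_size: int = 3
    pool_size: int = 2
    dropout: float = 0.5
    dense_units: int = 100
    epochs: int = 10
    batch_size: int = 10
    validation_split: float = 0.2
    test_fraction: float = 0.2
    early_stop_patience: int = 5
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.dropout, self.validation_split, self.test_fraction):
            if not (0.0 < frac < 1.0):
                raise ValueError("fractions must lie in (0, 1)")
        for count in (
            self.conv_filters,
            self.kernel_size,
            self.pool_size,
            self.dense_units,
            self.epochs,
            self.batch_size,
            self.early_stop_patience,
        ):
            if count < 1:
                raise ValueError("counts must be positive")


@dataclass
class TrainTestSplit:
    train_idx: np.ndarray
    test_idx: np.ndarray
    manifest: dict


@dataclass
class TrainResult:
    test_accuracy: float
    history: dict  # per-epoch train_loss / train_accuracy / val_accuracy
    config: ClassifierConfig
    seed: int
    split_manifest: dict
    epochs_run: int


def condition_label(condition: str) -> int:
    return {"A": 0, "B": 1}[condition]


def build_features(
    kind: str,
    epochs: list[SignalEpoch] | None = None,
    dpl_series: list[DPLSeries] | None = None,
    eig_series: list[LeadingEigenvectorSeries] | None = None,
    decimation: int = 1,
) -> FeatureSet:
    """Assemble one sample per retained time point for the requested kind.

    raw: channel values at every ``decimation``-th sample (F = N).
    dpl_flat: each retained dPL slice flattened row by row (F = N^2).
    eigenvector: the V1(t) rows (F = N).

    Standardisation is deferred to training (statistics from the training
    split only).
    """
    mats, labels, groups = [], [], []
    if kind == "raw":
        if not epochs:
            raise ValueError("raw features need epochs")
        n0 = epochs[0].n_channels
        for ep in epochs:
            if ep.n_channels != n0:
                raise ValueError("mixed channel counts")
            x = ep.data[:, ::decimation].T  # (T, N)
            mats.append(x)
            labels.append(np.full(len(x), condition_label(ep.condition)))
            groups.append(np.full(len(x), ep.subject_id, dtype=object))
    elif kind == "dpl_flat":
        if not dpl_series:
            raise ValueError("dpl_flat features need dpl_series")
        n0 = dpl_series[0].dpl.shape[0]
        for ds in dpl_series:
            if ds.dpl.shape[0] != n0:
                raise ValueError("mixed channel counts")
            x = ds.dpl[:, :, ::decimation]  # (N, N, T')
            flat = x.transpose(2, 0, 1).reshape(x.shape[2], -1)  # row-major per slice
            mats.append(flat)
            labels.append(np.full(len(flat), condition_label(ds.condition)))
            groups.append(np.full(len(flat), ds.subject_id, dtype=object))
    elif kind == "eigenvector":
        if not eig_series:
            raise ValueError("eigenvector features need eig_series")
        n0 = eig_series[0].vectors.shape[1]
        for es in eig_series:
            if es.vectors.shape[1] != n0:
                raise ValueError("mixed channel counts")
            x = es.vectors[::decimation]
            mats.append(x)
            labels.append(np.full(len(x), condition_label(es.condition)))
            groups.append(np.full(len(x), es.subject_id, dtype=object))
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    return FeatureSet(
        kind, np.vstack(mats), np.concatenate(labels), np.concatenate(groups)
    )


def split_data(
    features: FeatureSet,
    test_fraction: float = 0.2,
    seed: int = 0,
    group_aware: bool = True,
    max_redraws: int = 100,
) -> TrainTestSplit:
    """Train/test split; group-aware keeps each subject wholly on one side.

    The non-group mode is a stratified random split of samples.  Either way
    both classes must be present on both sides; degenerate draws are redrawn
    (seeded) with a logged warning.
    """
    rng = np.random.default_rng(seed)
    y = features.labels
    for attempt in range(max_redraws):
        if group_aware:
            subjects = np.array(sorted(set(features.grouping.tolist())))
            rng.shuffle(subjects)
            n_test = max(1, round(test_fraction * len(subjects)))
            test_subjects = set(subjects[:n_test].tolist())
            test_mask = np.array([g in test_subjects for g in features.grouping])
        else:
            idx = rng.permutation(len(y))
            n_test = max(1, round(test_fraction * len(y)))
            # stratify: allocate proportionally within each class
            test_mask = np.zeros(len(y), dtype=bool)
            for cls in (0, 1):
                cls_idx = idx[y[idx] == cls]
                k = max(1, round(test_fraction * len(cls_idx)))
                test_mask[cls_idx[:k]] = True
        train_idx = np.nonzero(~test_mask)[0]
        test_idx = np.nonzero(test_mask)[0]
        ok = (
            len(set(y[train_idx].tolist())) == 2 and len(set(y[test_idx].tolist())) == 2
        )
        if ok:
            if attempt:
                import warnings

                warnings.warn(f"split redrawn {attempt} time(s) to cover both classes")
            manifest = {
                "group_aware": group_aware,
                "test_fraction": test_fraction,
                "seed": seed,
                "n_train": int(len(train_idx)),
                "n_test": int(len(test_idx)),
                "test_subjects": sorted(set(features.grouping[test_idx].tolist())),
                "redraws": attempt,
            }
            return TrainTestSplit(train_idx, test_idx, manifest)
    raise ValueError("could not draw a split containing both classes on both sides")


class _Conv1DNet:
    """Forward/backward of the fixed small 1D-CNN, trained with Adam."""

    def __init__(self, n_features: int, cfg: ClassifierConfig, rng: np.random.Generator):
        k, nf = cfg.kernel_size, cfg.conv_filters
        if n_features < k:
            raise ValueError("fewer features than the convolution kernel")
        self.cfg = cfg
        self.l_conv = n_features - k + 1
        self.l_pool = self.l_conv // cfg.pool_size
        if self.l_pool < 1:
            raise ValueError("input too short for pooling")
        self.n_flat = self.l_pool * nf

        def glorot(shape, fan_in, fan_out):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        self.params = {
            "Wc": glorot((nf, k), k, k * nf),
            "bc": np.zeros(nf),
            "W1": glorot((self.n_flat, cfg.dense_units), self.n_flat, cfg.dense_units),
            "b1": np.zeros(cfg.dense_units),
            "W2": glorot((cfg.dense_units, 1), cfg.dense_units, 1),
            "b2": np.zeros(1),
        }
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Returns predictions and a cache for backprop.

        ``rng`` enables dropout (training mode); inference uses the identity
        (inverted dropout scaling keeps expectations aligned).
        """
        cfg = self.cfg
        p = self.params
        xw = sliding_window_view(x, cfg.kernel_size, axis=1)  # (B, Lc, k)
        zc = xw @ p["Wc"].T + p["bc"]  # (B, Lc, F)
        ac = np.maximum(zc, 0.0)
        lp, ps = self.l_pool, cfg.pool_size
        blocks = ac[:, : lp * ps].reshape(ac.shape[0], lp, ps, -1)
        arg = blocks.argmax(axis=2)
        pooled = blocks.max(axis=2)  # (B, Lp, F)
        if rng is not None:
            mask = (rng.random(pooled.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
        else:
            mask = np.ones_like(pooled)
        dropped = pooled * mask
        flat = dropped.reshape(dropped.shape[0], -1)
        z1 = flat @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        yhat = 1.0 / (1.0 + np.exp(-z2[:, 0]))
        cache = (x, xw, zc, blocks, arg, mask, flat, z1, a1)
        return yhat, cache

    def backward(self, yhat: np.ndarray, y: np.ndarray, cache) -> dict:
        cfg = self.cfg
        p = self.params
        x, xw, zc, blocks, arg, mask, flat, z1, a1 = cache
        batch = len(y)
        dz2 = ((yhat - y) / batch)[:, None]  # BCE + sigmoid
        grads = {
            "W2": a1.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (z1 > 0)
        grads["W1"] = flat.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ p["W1"].T
        ddropped = dflat.reshape(batch, self.l_pool, -1)
        dpooled = ddropped * mask
        # route through the argmax of each pooling block
        dblocks = np.zeros_like(blocks)
        b_idx, l_idx, f_idx = np.meshgrid(
            np.arange(batch), np.arange(self.l_pool), np.arange(blocks.shape[3]),
            indexing="ij",
        )
        dblocks[b_idx, l_idx, arg, f_idx] = dpooled
        dac = np.zeros_like(zc)
        dac[:, : self.l_pool * cfg.pool_size] = dblocks.reshape(
            batch, self.l_pool * cfg.pool_size, -1
        )
        dzc = dac * (zc > 0)  # (B, Lc, F)
        grads["Wc"] = np.einsum("blf,blk->fk", dzc, xw)
        grads["bc"] = dzc.sum(axis=(0, 1))
        return grads

    def adam_step(self, grads: dict) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-7
        self._adam_t += 1
        lr = self.cfg.learning_rate
        for key, g in grads.items():
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * g
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * g * g
            mhat = m / (1 - b1**self._adam_t)
            vhat = v / (1 - b2**self._adam_t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    def predict(self, x: np.ndarray) -> np.ndarray:
        yhat, _ = self.forward(x)
        return yhat


def _standardize_stats(x_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mu, sd


def train(
    features: FeatureSet,
    config: ClassifierConfig | None = None,
    split: TrainTestSplit | None = None,
    group_aware: bool = True,
) -> TrainResult:
    """Split, standardise on the training split, fit the CNN, score the test set."""
    cfg = config or ClassifierConfig()
    if split is None:
        split = split_data(features, cfg.test_fraction, cfg.seed, group_aware=group_aware)
    x, y = features.samples, features.labels.astype(float)
    if len(split.train_idx) < cfg.batch_size:
        raise ValueError("fewer training samples than the batch size")
    mu, sd = _standardize_stats(x[split.train_idx])
    xs = (x - mu) / sd

    rng = np.random.default_rng(config.seed if config else cfg.seed)
    # carve the validation split out of the training portion (seeded shuffle)
    tr = rng.permutation(split.train_idx)
    n_val = max(1, int(round(cfg.validation_split * len(tr))))
    val_idx, fit_idx = tr[:n_val], tr[n_val:]

    net = _Conv1DNet(x.shape[1], cfg, rng)
    history: dict[str, list[float]] = {"train_loss": [], "train_accuracy": [], "val_accuracy": []}
    best_val, since_best = -np.inf, 0
    epochs_run = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(fit_idx)
        losses = []
        correct = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            yhat, cache = net.forward(xs[batch], rng=rng)
            eps = 1e-12
            losses.append(
                float(-np.mean(y[batch] * np.log(yhat + eps) + (1 - y[batch]) * np.log(1 - yhat + eps)))
            )
            correct += int(((yhat >= 0.5) == (y[batch] >= 0.5)).sum())
            grads = net.backward(yhat, y[batch], cache)
            net.adam_step(grads)
        epochs_run += 1
        val_pred = net.predict(xs[val_idx])
        val_acc = float(((val_pred >= 0.5) == (y[val_idx] >= 0.5)).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_accuracy"].append(correct / len(order))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_val:
            best_val, since_best = val_acc, 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    test_pred = net.predict(xs[split.test_idx])
    test_acc = float(((test_pred >= 0.5) == (y[split.test_idx] >= 0.5)).mean())
    return TrainResult(test_acc, history, cfg, cfg.seed, split.manifest, epochs_run)


def compare_feature_sets(
    feature_sets: dict[str, FeatureSet],
    config: ClassifierConfig | None = None,
    n_seeds: int = 5,
    group_aware: bool = True,
) -> pd.DataFrame:
    """Mean +/- sd test accuracy per feature kind over ``n_seeds`` seeded runs."""
    cfg = config or ClassifierConfig()
    rows = []
    for kind in FEATURE_KINDS:
        if kind not in feature_sets:
            continue
        accs = []
        for s in range(n_seeds):
            run_cfg = replace(cfg, seed=cfg.seed + s)
            accs.append(train(feature_sets[kind], run_cfg, group_aware=group_aware).test_accuracy)
        rows.append(
            {
                "kind": kind,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "n_seeds": n_seeds,
            }
        )
    return pd.DataFrame(rows).sort_values("mean_accuracy", ascending=False, ignore_index=True)
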