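"""Permutation inference on state occupancy, with FDR and Bonferroni control.

The occupancy of every PL state is compared between the two conditions with
a Welch two-sample t statistic whose reference distribution is built by
permutation: condition labels are shuffled (by default within subject, since
every subject contributes both conditions), the statistic recomputed per
iteration, and the two-sided p-value taken as the fraction of null
statistics at least as extreme as the observed one, with the standard +1
finite-permutation correction.  Across states the raw p-values receive a
Benjamini-Hochberg FDR adjustment; a Bonferroni adjuster is provided for
the graph-metric family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .states import StateMetrics, occupancy_matrix


@dataclass
class OccupancyContrast:
    """Paired per-subject occupancy samples for conditions A and B.

    ``a`` and ``b`` are (n_subjects, n_states) with matching subject rows.
    """

    a: np.ndarray
    b: np.ndarray
    state_ids: list[int]
    subjects: list[str]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("conditions must share the subject set and states")
        if self.a.ndim == 1:
            self.a = self.a[:, None]
            self.b = self.b[:, None]
        if np.any((self.a < 0) | (self.a > 1) | (self.b < 0) | (self.b > 1)):
            raise ValueError("occupancies must lie in [0, 1]")


@dataclass
class PermutationTestResult:
    state: int
    observed_t: float
    p_raw: float
    p_fdr: float
    n_perm: int
    seed: int
    scheme: str
    null_t: np.ndarray | None = None


def contrast_from_metrics(metrics: StateMetrics) -> OccupancyContrast:
    """Build the paired A/B occupancy contrast from tidy state metrics."""
    occ_a = occupancy_matrix(metrics, "A")
    occ_b = occupancy_matrix(metrics, "B")
    if list(occ_a.index) != list(occ_b.index):
        raise ValueError("subject sets differ between conditions")
    return OccupancyContrast(
        occ_a.to_numpy(), occ_b.to_numpy(), list(occ_a.columns), list(occ_a.index)
    )


def two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch (unequal-variance) t statistic, positive when mean(b) > mean(a).

    Degenerate inputs: zero variance in both groups yields 0 for equal means
    and a signed infinity otherwise (flagged by the inf value itself).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    diff = b.mean() - a.mean()
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0.0:
        return 0.0 if diff == 0.0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(se2))


def _welch_t_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t along axis -2 (subjects) for stacked permutation draws."""
    n_a = a.shape[-2]
    n_b = b.shape[-2]
    diff = b.mean(axis=-2) - a.mean(axis=-2)
    se2 = a.var(axis=-2, ddof=1) / n_a + b.var(axis=-2, ddof=1) / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        t = np.where(se2 == 0.0, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    return t


def permutation_test(
    contrast: OccupancyContrast,
    n_perm: int = 10_000,
    seed: int = 0,
    scheme: str = "paired",
    keep_null: bool = False,
) -> list[PermutationTestResult]:
    """Per-state two-sided permutation test with FDR adjustment across states.

    ``scheme="paired"`` (default) flips each subject's A/B pair with
    probability 1/2 per iteration — the exchangeability that matches a
    within-subject two-condition design.  ``scheme="unpaired"`` reshuffles
    all 2n epoch labels freely, matching a literal two-independent-samples
    reading.  p_raw = (1 + #{|t_null| >= |t_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values")
    if scheme not in ("paired", "unpaired"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    a, b = contrast.a, contrast.b  # (n, k)
    n, k = a.shape
    t_obs = _welch_t_batch(a, b)  # (k,)

    if scheme == "paired":
        flips = rng.random((n_perm, n, 1)) < 0.5
        a_null = np.where(flips, b[None], a[None])  # (n_perm, n, k)
        b_null = np.where(flips, a[None], b[None])
    else:
        pooled = np.concatenate([a, b], axis=0)  # (2n, k)
        perms = np.argsort(rng.random((n_perm, 2 * n)), axis=1)
        shuffled = pooled[perms]  # (n_perm, 2n, k)
        a_null, b_null = shuffled[:, :n], shuffled[:, n:]
    t_null = _welch_t_batch(a_null, b_null)  # (n_perm, k)

    exceed = (np.abs(t_null) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p_raw = (1.0 + exceed) / (n_perm + 1.0)
    p_fdr = fdr_adjust(p_raw)
    return [
        PermutationTestResult(
            state=contrast.state_ids[j],
            observed_t=float(t_obs[j]),
            p_raw=float(p_raw[j]),
            p_fdr=float(p_fdr[j]),
            n_perm=n_perm,
            seed=seed,
            scheme=scheme,
            null_t=t_null[:, j].copy() if keep_null else None,
        )
        for j in range(k)
    ]


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values) -> np.ndarray:
    """min(1, p * m) per value."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p * p.size)


def results_frame(results: list[PermutationTestResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "state": r.state,
                "t_obs": r.observed_t,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "n_perm": r.n_perm,
                "seed": r.seed,
                "scheme": r.scheme,
            }
            for r in results
        ]
    )
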