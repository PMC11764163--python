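"""Instantaneous phase, dynamic phase-locking tensors, and leading eigenvectors.

The LEiDA front end: a band-limited multichannel epoch is converted to an
analytic signal per channel (Hilbert transform), written in polar form
``x(t) = A(t) cos(theta(t))``.  At every retained sample the dynamic
phase-locking matrix

    dPL(n, p, t) = cos(theta(n, t) - theta(p, t))

captures the instantaneous phase alignment of every channel pair (1 for
in-phase, 0 for orthogonal, -1 for anti-phase).  Each N x N slice is then
summarised by its leading eigenvector V1(t) — the unit eigenvector of the
largest-magnitude eigenvalue — which carries the dominant phase-alignment
pattern into the clustering stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt


class DegenerateInputError(ValueError):
    """Raised when an input channel carries no usable signal."""


@dataclass
class SignalEpoch:
    """One subject/condition multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Real-valued signal, channels in rows.
    sampling_rate : float
        Samples per second (Hz).
    channel_labels : list of str
        Unique channel names.
    subject_id : str
    condition : str
        Condition code, ``"A"`` (non-social) or ``"B"`` (social).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    subject_id: str = "S0"
    condition: str = "A"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if self.data.shape[1] < 4:
            raise ValueError("need at least 4 samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length mismatch")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class PhaseTensor:
    """Instantaneous phase and envelope of an analytic signal.

    ``theta`` holds phases in (-pi, pi]; ``amplitude`` the non-negative
    envelope.  ``cos(theta) * amplitude`` reconstructs the input away from
    the epoch edges.
    """

    theta: np.ndarray
    amplitude: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    subject_id: str = "S0"
    condition: str = "A"

    def __post_init__(self) -> None:
        if self.theta.shape != self.amplitude.shape:
            raise ValueError("theta and amplitude shapes differ")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    def trimmed(self, n_edge: int) -> "PhaseTensor":
        """Drop ``n_edge`` samples from each end (Hilbert edge artifacts)."""
        if n_edge <= 0:
            return self
        if 2 * n_edge >= self.theta.shape[1]:
            raise ValueError("trim longer than epoch")
        return PhaseTensor(
            self.theta[:, n_edge:-n_edge],
            self.amplitude[:, n_edge:-n_edge],
            self.sampling_rate,
            self.channel_labels,
            self.subject_id,
            self.condition,
        )


@dataclass
class DPLSeries:
    """N x N x T dynamic phase-locking tensor with its channel/time metadata."""

    dpl: np.ndarray
    channel_labels: list[str]
    time_index: np.ndarray
    subject_id: str = "S0"
    condition: str = "A"

    def __post_init__(self) -> None:
        n, p, t = self.dpl.shape
        if n != p:
            raise ValueError("dPL slices must be square")
        if len(self.time_index) != t:
            raise ValueError("time_index length mismatch")


@dataclass
class LeadingEigenvectorSeries:
    """Per-time-point leading eigenvectors V1(t) (rows) and their eigenvalues."""

    vectors: np.ndarray
    eigenvalues: np.ndarray
    channel_labels: list[str]
    time_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = "S0"
    condition: str = "A"

    def __post_init__(self) -> None:
        if self.time_index is None:
            self.time_index = np.arange(self.vectors.shape[0])
        if self.vectors.shape[0] != len(self.eigenvalues):
            raise ValueError("eigenvalues length mismatch")


def bandpass_filter(epoch: SignalEpoch, low: float, high: float, order: int = 4) -> SignalEpoch:
    """Zero-phase Butterworth band-pass per channel.

    ``low`` and ``high`` are the band edges in Hz and must satisfy
    ``0 < low < high < sampling_rate / 2``.  Filtering is forward-backward
    (``sosfiltfilt``), so the output has no phase distortion and the DC
    component is removed.
    """
    nyq = epoch.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); got ({low}, {high})"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=epoch.sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, epoch.data, axis=1)
    return SignalEpoch(
        filtered, epoch.sampling_rate, list(epoch.channel_labels), epoch.subject_id, epoch.condition
    )


def instantaneous_phase(epoch: SignalEpoch) -> PhaseTensor:
    """Analytic-signal phase and envelope per channel via the Hilbert transform.

    The caller is responsible for band-limiting the input first.  A constant
    channel has no defined phase and raises :class:`DegenerateInputError`
    naming the offending channel.
    """
    ptp = np.ptp(epoch.data, axis=1)
    flat = np.nonzero(ptp == 0.0)[0]
    if flat.size:
        raise DegenerateInputError(
            f"constant channel(s) have no instantaneous phase: "
            f"{[epoch.channel_labels[i] for i in flat]}"
        )
    analytic = hilbert(epoch.data, axis=1)
    return PhaseTensor(
        np.angle(analytic),
        np.abs(analytic),
        epoch.sampling_rate,
        list(epoch.channel_labels),
        epoch.subject_id,
        epoch.condition,
    )


def compute_dpl(phase: PhaseTensor, decimation: int = 1) -> DPLSeries:
    """Dynamic phase-locking tensor dPL(n, p, t) = cos(theta_n(t) - theta_p(t)).

    One slice per retained sample; ``decimation`` keeps every d-th sample
    (default 1 = every sample).  Slices are exactly symmetric with unit
    diagonal and entries in [-1, 1].
    """
    if decimation < 1:
        raise ValueError("decimation must be >= 1")
    theta = phase.theta[:, ::decimation]
    if theta.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    diff = theta[:, None, :] - theta[None, :, :]
    dpl = np.cos(diff)
    # enforce the exact invariants against floating asymmetry
    dpl = 0.5 * (dpl + dpl.transpose(1, 0, 2))
    idx = np.arange(theta.shape[0])
    dpl[idx, idx, :] = 1.0
    time_index = np.arange(phase.theta.shape[1])[::decimation]
    return DPLSeries(dpl, list(phase.channel_labels), time_index, phase.subject_id, phase.condition)


def apply_sign_convention(vectors: np.ndarray) -> np.ndarray:
    """Fix the eigenvector sign: the majority of elements must be negative.

    Eigenvectors are defined up to sign; clustering needs one deterministic
    representative.  Each row is flipped when it has more positive than
    negative elements; an exact tie is resolved by forcing the first element
    non-positive.  The rule is idempotent.
    """
    v = np.array(vectors, dtype=float, copy=True)
    if v.ndim == 1:
        return apply_sign_convention(v[None, :])[0]
    n_pos = (v > 0).sum(axis=1)
    n_neg = (v < 0).sum(axis=1)
    flip = n_pos > n_neg
    tie = n_pos == n_neg
    flip |= tie & (v[:, 0] > 0)
    v[flip] *= -1.0
    return v


def leading_eigenvector(dpl: DPLSeries) -> LeadingEigenvectorSeries:
    """Leading eigenvector V1(t) of every dPL slice.

    Uses a batched symmetric eigendecomposition; per slice the eigenvector of
    the largest-magnitude eigenvalue is taken, normalised to unit Euclidean
    norm, with the deterministic sign convention applied.
    """
    slices = np.ascontiguousarray(dpl.dpl.transpose(2, 0, 1))  # (T, N, N)
    try:
        w, v = np.linalg.eigh(slices)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - LAPACK failure
        raise RuntimeError(f"eigendecomposition failed within epoch: {exc}") from exc
    # eigh sorts ascending; the largest magnitude is either end
    take_last = np.abs(w[:, -1]) >= np.abs(w[:, 0])
    idx = np.where(take_last, w.shape[1] - 1, 0)
    rows = np.arange(slices.shape[0])
    eigvals = w[rows, idx]
    vecs = v[rows, :, idx]
    vecs = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    vecs = apply_sign_convention(vecs)
    return LeadingEigenvectorSeries(
        vecs, eigvals, list(dpl.channel_labels), np.asarray(dpl.time_index),
        dpl.subject_id, dpl.condition,
    )


def epoch_to_eigenvectors(
    epoch: SignalEpoch,
    band: tuple[float, float] = (1.0, 40.0),
    carrier_freq: float = 10.0,
    decimation: int = 1,
    edge_periods: int = 1,
) -> tuple[LeadingEigenvectorSeries, DPLSeries]:
    """Convenience chain: band-pass -> Hilbert -> edge trim -> dPL -> V1(t).

    ``edge_periods`` carrier periods are discarded at each epoch edge before
    the dPL tensor is formed, clearing Hilbert edge artifacts.
    """
    filtered = bandpass_filter(epoch, *band)
    pt = instantaneous_phase(filtered)
    n_edge = int(round(edge_periods * epoch.sampling_rate / carrier_freq))
    pt = pt.trimmed(n_edge)
    dpl = compute_dpl(pt, decimation=decimation)
    return leading_eigenvector(dpl), dpl


def save_eigenvectors(series: LeadingEigenvectorSeries, path) -> None:
    """Write a compressed array file with a JSON metadata header."""
    header = json.dumps(
        {
            "channel_labels": series.channel_labels,
            "subject_id": series.subject_id,
            "condition": series.condition,
            "sign_convention": "majority-negative/tie-first-nonpositive",
        }
    )
    np.savez_compressed(
        path,
        vectors=series.vectors,
        eigenvalues=series.eigenvalues,
        time_index=series.time_index,
        header=np.array(header),
    )


def load_eigenvectors(path) -> LeadingEigenvectorSeries:
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        return LeadingEigenvectorSeries(
            npz["vectors"],
            npz["eigenvalues"],
            header["channel_labels"],
            npz["time_index"],
            header["subject_id"],
            header["condition"],
        )
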