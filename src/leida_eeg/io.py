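"""File I/O: minimal EDF writing, TSV matrices, and manifests.

EDF (European Data Format) stores multichannel recordings as 16-bit integers
with per-signal physical scaling.  No EDF writer is available as a library
dependency, so a small single-purpose writer lives here; it emits plain EDF
(one header, fixed-length data records) that standard readers, including
:func:`mne.io.read_raw_edf`, accept.  Reading EDF goes through MNE.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_EDF_RECORD_BYTE_LIMIT = 61440  # recommended maximum data-record size


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _pick_samples_per_record(n_samples: int, n_channels: int) -> int:
    """Largest divisor of n_samples keeping a record under the EDF size limit."""
    limit = max(1, _EDF_RECORD_BYTE_LIMIT // (2 * n_channels))
    for spr in range(min(limit, n_samples), 0, -1):
        if n_samples % spr == 0:
            return spr
    return 1


def write_edf(path, data: np.ndarray, sampling_rate: float, channel_labels: list[str]) -> None:
    """Write a channels x samples float matrix as a 16-bit EDF file.

    Physical scaling spans each channel's observed range, so round trips are
    exact up to the 16-bit quantization step.  Values are recorded in
    microvolts (physical dimension ``uV``).
    """
    data = np.asarray(data, dtype=float)
    n_channels, n_samples = data.shape
    if len(channel_labels) != n_channels:
        raise ValueError("label count mismatch")
    spr = _pick_samples_per_record(n_samples, n_channels)
    n_records = n_samples // spr
    duration = spr / sampling_rate

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax == pmin
    pmax = np.where(flat, pmin + 1.0, pmax)  # avoid zero physical span
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate 01-JAN-2024 X X X", 80),
            _ascii_field("01.01.24", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (n_channels + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(f"{duration:.6f}"[:8].rstrip("."), 8),
            _ascii_field(n_channels, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_ascii_field(lbl, 16) for lbl in channel_labels),
            b"".join(_ascii_field("", 80) for _ in channel_labels),
            b"".join(_ascii_field("uV", 8) for _ in channel_labels),
            b"".join(_ascii_field(f"{v:.6g}"[:8], 8) for v in pmin),
            b"".join(_ascii_field(f"{v:.6g}"[:8], 8) for v in pmax),
            b"".join(_ascii_field(dmin, 8) for _ in channel_labels),
            b"".join(_ascii_field(dmax, 8) for _ in channel_labels),
            b"".join(_ascii_field("", 80) for _ in channel_labels),
            b"".join(_ascii_field(spr, 8) for _ in channel_labels),
            b"".join(_ascii_field("", 32) for _ in channel_labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE; returns (data_uV, sampling_rate, labels)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def write_tsv_matrix(path, data: np.ndarray, channel_labels: list[str]) -> None:
    """Channels x samples TSV, one row per channel, label in the first column."""
    df = pd.DataFrame(np.asarray(data, dtype=float))
    df.insert(0, "channel", channel_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tsv_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = df["channel"].tolist()
    return df.drop(columns="channel").to_numpy(dtype=float), labels


def write_manifest(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject": str, "condition": str})


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
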