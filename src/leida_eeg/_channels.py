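"""Standard 10-20 / 10-10 channel naming helpers."""

# 64-electrode layout of a typical 64-channel 10-10 cap (no EOG/reference).
STANDARD_64 = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "M1", "T7", "C3", "Cz",
    "C4", "T8", "M2", "CP5", "CP1", "CP2", "CP6", "P7",
    "P3", "Pz", "P4", "P8", "POz", "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FC3", "FCz", "FC4", "C5", "C1", "C2", "C6", "CP3",
    "CPz", "CP4", "P5", "P1", "P2", "P6", "PO5", "PO3",
    "PO4", "PO6", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
]

assert len(STANDARD_64) == 64 and len(set(STANDARD_64)) == 64


def default_labels(n_channels: int) -> list[str]:
    """Return ``n_channels`` distinct electrode-style labels.

    The first 64 follow the 10-10 extension of the international 10-20
    system; beyond that, generic ``CH{i}`` names are appended.
    """
    if n_channels <= len(STANDARD_64):
        return STANDARD_64[:n_channels]
    extra = [f"CH{i}" for i in range(len(STANDARD_64), n_channels)]
    return STANDARD_64 + extra
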