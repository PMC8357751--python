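"""Electrode montages (extended international 10-20 labels).

The full montage mirrors a common 64-channel cap plus the online
reference FCz (65 labels total).  A reduced 32-channel montage keeps
every electrode used by the midline regions of interest and is intended
for fast simulation runs.
"""

from __future__ import annotations

# 64 recording electrodes + FCz online reference
MONTAGE_65: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "FCz",
)

# Reduced montage: the 21 ROI electrodes (incl. FCz) + 11 lateral sites
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F1", "F2", "F4", "F8",
    "FC1", "FC2", "T7", "C3", "Cz", "C1", "C2", "C4",
    "CPz", "CP1", "CP2", "P3", "Pz", "P1", "P2",
    "POz", "PO3", "PO4", "O1", "Oz", "O2", "T8",
    "FCz",
)

DEFAULT_REFERENCE = "FCz"


def default_montage(n_channels: int) -> list[str]:
    """Return the standard label list for a supported channel count."""
    if n_channels == 65:
        return list(MONTAGE_65)
    if n_channels == 32:
        return list(MONTAGE_32)
    if n_channels <= len(MONTAGE_65):
        # generic fallback: truncate the full montage but keep FCz last
        labels = [c for c in MONTAGE_65 if c != DEFAULT_REFERENCE]
        return labels[: n_channels - 1] + [DEFAULT_REFERENCE]
    raise ValueError(
        f"no montage with {n_channels} channels; at most {len(MONTAGE_65)} supported"
    )
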