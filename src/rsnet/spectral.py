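"""Epoch-averaged power spectral density, band powers and ROI aggregation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .bands import Band, BandSet
from .containers import EpochSet

__all__ = ["Band", "BandSet", "RoiSet", "Spectrum", "psd", "band_roi_power"]


DEFAULT_ROIS: dict[str, tuple[str, ...]] = {
    "frontal": ("FCz", "FC1", "FC2", "Fz", "F1", "F2"),
    "central": ("Cz", "C1", "C2", "CPz", "CP1", "CP2"),
    "parietal": ("Pz", "P1", "P2", "POz", "PO3", "PO4"),
    "occipital": ("Oz", "O1", "O2"),
}


class RoiSet:
    """Named, disjoint electrode groups over which band power is averaged."""

    def __init__(self, rois: dict[str, tuple[str, ...]] | None = None):
        self.rois = {k: tuple(v) for k, v in (rois or DEFAULT_ROIS).items()}
        seen: set[str] = set()
        for name, members in self.rois.items():
            if not members:
                raise ValueError(f"ROI {name!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"ROIs overlap on electrodes {sorted(overlap)}")
            seen |= set(members)

    def validate_montage(self, channel_names: list[str]) -> None:
        missing = sorted(seen for members in self.rois.values()
                         for seen in members if seen not in channel_names)
        if missing:
            raise KeyError(f"montage lacks ROI electrodes: {missing}")

    def items(self):
        return self.rois.items()

    @classmethod
    def default(cls) -> "RoiSet":
        return cls()


@dataclass
class Spectrum:
    """Epoch-averaged per-channel power spectral density (uV^2/Hz)."""

    freqs: np.ndarray           # (n_bins,)
    power: np.ndarray           # (n_channels, n_bins)
    channel_names: list[str]
    resolution: float           # Hz per bin


def psd(epochs: EpochSet, fmin: float = 3.0, fmax: float = 30.0) -> Spectrum:
    """Hann-tapered periodogram per epoch, averaged over epochs.

    One FFT segment per epoch, so the frequency resolution is
    ``1 / epoch_len_s`` (0.125 Hz for 8 s epochs).  The returned spectrum
    is restricted to [fmin, fmax].
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty EpochSet")
    freqs, pxx = signal.periodogram(epochs.data, fs=epochs.fs,
                                    window="hann", axis=-1)
    mean_pxx = pxx.mean(axis=0)  # average over epochs
    mask = (freqs >= fmin) & (freqs <= fmax)
    return Spectrum(
        freqs=freqs[mask],
        power=mean_pxx[:, mask],
        channel_names=list(epochs.channel_names),
        resolution=float(freqs[1] - freqs[0]),
    )


def band_roi_power(
    spectrum: Spectrum,
    bands: BandSet | None = None,
    rois: RoiSet | None = None,
    subject_id: str = "",
    condition: str = "",
) -> pd.DataFrame:
    """Aggregate a spectrum into band x ROI absolute and log10 power.

    Band power of a channel is the mean PSD over bins whose center lies
    in the half-open interval [low, high); the ROI value is the mean over
    member electrodes.  Returns a tidy table with columns
    (subject, condition, roi, band, abs_power, log10_power, resolution).
    """
    bands = bands or BandSet.default()
    rois = rois or RoiSet.default()
    rois.validate_montage(spectrum.channel_names)
    idx = {c: i for i, c in enumerate(spectrum.channel_names)}

    rows = []
    for roi_name, members in rois.items():
        chan_rows = spectrum.power[[idx[m] for m in members]]
        for band in bands:
            mask = (spectrum.freqs >= band.low) & (spectrum.freqs < band.high)
            if not mask.any():
                raise ValueError(f"no PSD bins inside band {band.name}")
            p = float(chan_rows[:, mask].mean())
            rows.append({
                "subject": subject_id,
                "condition": condition,
                "roi": roi_name,
                "band": band.name,
                "abs_power": p,
                "log10_power": float(np.log10(p)) if p > 0 else -np.inf,
                "resolution": spectrum.resolution,
            })
    return pd.DataFrame(rows)
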