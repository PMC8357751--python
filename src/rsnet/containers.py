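"""Core data containers: continuous recordings and epoched data.

A :class:`Recording` is one subject-by-condition block of continuous
multichannel EEG (channels x samples, microvolts).  An :class:`EpochSet`
holds the fixed-length, possibly overlapping segments cut from a
recording; it is the unit every downstream estimator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class Recording:
    """Continuous multichannel signal block.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique 10-20 style labels, one per row of ``data``.
    reference : str
        Label of the online reference electrode, or ``"common-average"``
        after re-referencing.
    subject_id, condition : str
        Cohort metadata.
    meta : dict
        Free-form provenance (applied processing, generator parameters).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    reference: str = "common-average"
    subject_id: str = ""
    condition: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        names = list(self.channel_names)
        if len(names) != self.data.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {self.data.shape[0]} data rows"
            )
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        self.channel_names = names

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray | None = None, **kw: Any) -> "Recording":
        """Shallow metadata copy with replaced fields (data is not shared)."""
        out = Recording(
            data=np.array(self.data if data is None else data, dtype=np.float64),
            fs=kw.pop("fs", self.fs),
            channel_names=kw.pop("channel_names", list(self.channel_names)),
            reference=kw.pop("reference", self.reference),
            subject_id=kw.pop("subject_id", self.subject_id),
            condition=kw.pop("condition", self.condition),
            meta=dict(self.meta),
        )
        out.meta.update(kw.pop("meta", {}))
        if kw:
            raise TypeError(f"unknown fields: {sorted(kw)}")
        return out


@dataclass
class EpochSet:
    """Fixed-length overlapping epochs cut from one recording.

    ``data`` has shape (n_epochs, n_channels, n_samples_per_epoch).
    ``provenance`` records the preprocessing configuration and source
    recording metadata so downstream outputs are auditable.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_len_s(self) -> float:
        return self.data.shape[2] / self.fs
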