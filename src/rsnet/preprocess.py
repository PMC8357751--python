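"""Signal conditioning: notch, FIR band-pass, re-referencing, resampling, epoching.

The chain is deterministic and zero-phase throughout (filters are applied
forward-backward), because downstream phase-lag connectivity estimates are
meaningless if the preprocessing itself distorts phase.  The stage order
follows the conventional resting-state chain: line-noise notch, band-pass,
common-average re-reference (with the online reference electrode
recomputed), polyphase resampling, epoching.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the conditioning chain.

    Defaults reproduce a 500 Hz acquisition pipeline: 60/120 Hz notch,
    3-40 Hz FIR band-pass, downsampling to 256 Hz, 8 s epochs with 4 s
    overlap, first 50 epochs retained.  ``reject_uV`` optionally drops
    epochs whose absolute amplitude exceeds the threshold before the
    first-``max_epochs`` selection.
    """

    notch_freqs: tuple[float, ...] = (60.0, 120.0)
    bp_low: float = 3.0
    bp_high: float = 40.0
    target_fs: float = 256.0
    epoch_len_s: float = 8.0
    epoch_overlap_s: float = 4.0
    max_epochs: int = 50
    reject_uV: float | None = None

    def validate(self) -> None:
        if not 0 < self.bp_low < self.bp_high:
            raise ValueError("need 0 < bp_low < bp_high")
        if self.bp_high >= self.target_fs / 2:
            raise ValueError("bp_high must be below the target Nyquist frequency")
        if not 0 <= self.epoch_overlap_s < self.epoch_len_s:
            raise ValueError("epoch_overlap_s must be in [0, epoch_len_s)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def notch_filter(rec: Recording, freqs: tuple[float, ...] | list[float]) -> Recording:
    """Zero-phase IIR notch at each mains frequency (>= 30 dB rejection)."""
    freqs = tuple(freqs)
    if not freqs:
        return rec.copy_with(meta={"notch": []})
    data = rec.data
    for f in freqs:
        if f >= rec.fs / 2:
            raise ValueError(f"notch frequency {f} Hz >= Nyquist ({rec.fs / 2} Hz)")
        # narrow stop band; filtfilt squares the response, deepening the notch
        b, a = signal.iirnotch(f, Q=30.0, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    return rec.copy_with(data=data, meta={"notch": list(freqs)})


def _fir_bandpass_taps(low: float, high: float, fs: float) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass; transition width 25% of the low edge."""
    trans = 0.25 * low
    # Hamming window needs ~3.3 / (normalized transition width) taps
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += numtaps % 2  # even order -> odd tap count, symmetric type-I FIR
    numtaps += 1
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs,
                         window="hamming")


def bandpass_fir(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase FIR band-pass; removes DC.

    The filter is linear-phase (symmetric windowed sinc) and applied via
    FFT convolution with exact group-delay compensation, which is
    equivalent to zero-phase filtering.
    """
    if not 0 < low < high < rec.fs / 2:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    taps = _fir_bandpass_taps(low, high, rec.fs)
    # remove DC explicitly: the stop band guarantees it asymptotically but
    # edge truncation would otherwise leak a residual at the boundaries
    data = rec.data - rec.data.mean(axis=-1, keepdims=True)
    data = signal.fftconvolve(data, taps[None, :], mode="same", axes=-1)
    return rec.copy_with(data=data, meta={"bandpass": (low, high),
                                          "fir_numtaps": len(taps)})


def rereference_common_average(rec: Recording) -> Recording:
    """Common-average re-reference, reinstating the online reference channel.

    The reference electrode carried no data row while recording (its
    potential is the zero of the montage); it is appended as an explicit
    zero channel, then the instantaneous across-channel mean is removed
    from every channel.  The per-sample channel sum of the output is 0.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels for common-average reference")
    names = list(rec.channel_names)
    data = rec.data
    if rec.reference != "common-average":
        if rec.reference in names:
            raise ValueError(
                f"reference {rec.reference!r} already present as a data channel"
            )
        if not rec.reference:
            raise ValueError("recording has no reference label")
        names = names + [rec.reference]
        data = np.vstack([data, np.zeros((1, rec.n_samples))])
    data = data - data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, channel_names=names,
                         reference="common-average",
                         meta={"rereferenced": True})


def resample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase anti-aliased resampling to ``target_fs`` (downsampling only)."""
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if target_fs == rec.fs:
        return rec.copy_with(meta={"resampled": rec.fs})
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=-1)
    return rec.copy_with(data=data, fs=target_fs,
                         meta={"resampled": target_fs})


def epoch(rec: Recording, cfg: PreprocessConfig) -> EpochSet:
    """Cut overlapping fixed-length epochs and keep the first ``max_epochs``.

    Epochs start at multiples of ``epoch_len_s - epoch_overlap_s`` from
    sample 0; a final incomplete epoch is dropped.  If ``reject_uV`` is
    set, epochs containing any sample beyond the threshold are removed
    before the first-``max_epochs`` selection; falling short of
    ``max_epochs`` is recorded in provenance, not an error.
    """
    cfg.validate()
    n_len = int(round(cfg.epoch_len_s * rec.fs))
    n_step = int(round((cfg.epoch_len_s - cfg.epoch_overlap_s) * rec.fs))
    if rec.n_samples < n_len:
        raise ValueError("recording shorter than one epoch")
    starts = np.arange(0, rec.n_samples - n_len + 1, n_step)
    epochs = np.stack([rec.data[:, s:s + n_len] for s in starts])
    n_candidates = len(starts)

    n_rejected = 0
    if cfg.reject_uV is not None:
        keep = np.abs(epochs).max(axis=(1, 2)) <= cfg.reject_uV
        n_rejected = int((~keep).sum())
        epochs = epochs[keep]

    warning = None
    if len(epochs) < cfg.max_epochs:
        warning = (f"only {len(epochs)} epochs available after rejection, "
                   f"wanted {cfg.max_epochs}")
    epochs = epochs[: cfg.max_epochs]

    prov = {
        "config": cfg,
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "n_candidate_epochs": n_candidates,
        "n_rejected": n_rejected,
        "source_meta": dict(rec.meta),
    }
    if warning:
        prov["warning"] = warning
    return EpochSet(data=epochs, fs=rec.fs,
                    channel_names=list(rec.channel_names), provenance=prov)


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Full deterministic chain: notch -> band-pass -> CAR -> resample -> epoch."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    out = notch_filter(rec, cfg.notch_freqs)
    out = bandpass_fir(out, cfg.bp_low, cfg.bp_high)
    out = rereference_common_average(out)
    out = resample(out, cfg.target_fs)
    es = epoch(out, cfg)
    es.provenance["stage_order"] = [
        "notch", "bandpass", "rereference", "resample", "epoch"
    ]
    return es
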