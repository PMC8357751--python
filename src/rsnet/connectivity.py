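"""Weighted phase lag index (wPLI) connectivity, per epoch and per band.

For two analytic signals z_i(t), z_j(t) the per-epoch estimate is

    wPLI_ij = | sum_t Im(z_i(t) conj(z_j(t))) |  /  sum_t | Im(z_i conj(z_j)) |

with 0/0 defined as 0 (no detectable lagged interaction).  The statistic
lies in [0, 1]; it is 1 when every sample's imaginary cross-spectrum has
the same sign (a persistent, asymmetric phase lag) and 0 for zero-lag
(volume-conducted) relations, whose cross-spectrum is purely real.  It is
invariant to per-channel amplitude scaling.

The epoch is band-pass filtered, converted to its analytic signal via the
Hilbert transform, and trimmed at both ends before the statistic is
accumulated, so filter/Hilbert edge artifacts do not enter the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal

from .bands import Band, BandSet
from .containers import EpochSet

try:  # pragma: no cover
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_TRIM_S = 0.5


@dataclass
class ConnectivityStack:
    """Per-band, per-epoch symmetric wPLI matrices.

    ``data`` has shape (n_bands, n_epochs, n_channels, n_channels); every
    matrix is symmetric with zero diagonal and entries in [0, 1].
    ``norm_scope`` records whether (and how) min-max normalization was
    applied, together with the min/max actually used.
    """

    data: np.ndarray
    bands: list[Band]
    channel_names: list[str]
    norm_scope: str = "none"
    norm_min: float | None = None
    norm_max: float | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def band_index(self, name: str) -> int:
        for i, b in enumerate(self.bands):
            if b.name == name:
                return i
        raise KeyError(name)


# --------------------------------------------------------------------------
# core estimator
# --------------------------------------------------------------------------

_ZERO_IMAG_RTOL = 1e-9  # Im mass below this fraction of |X| counts as 0/0


def _wpli_from_imag_py(u: np.ndarray, v: np.ndarray,
                       a: np.ndarray) -> np.ndarray:
    """wPLI matrix from real/imag parts and moduli of analytic signals.

    ``a[i, t]`` is |z_i(t)|.  A pair whose total imaginary cross-spectral
    mass is numerically zero relative to its total cross-spectral
    magnitude scores 0 (the 0/0 convention: no detectable lagged
    interaction).
    """
    n = u.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = 0.0
            den = 0.0
            mag = 0.0
            for t in range(u.shape[1]):
                im = v[i, t] * u[j, t] - u[i, t] * v[j, t]
                num += im
                den += abs(im)
                mag += a[i, t] * a[j, t]
            w = abs(num) / den if den > _ZERO_IMAG_RTOL * mag else 0.0
            out[i, j] = w
            out[j, i] = w
    return out


if _HAVE_NUMBA:
    _wpli_from_imag = njit(cache=True)(_wpli_from_imag_py)
else:  # pragma: no cover
    _wpli_from_imag = _wpli_from_imag_py


def wpli_from_analytic(z: np.ndarray) -> np.ndarray:
    """wPLI of pre-computed analytic signals, shape (n_channels, n_samples)."""
    z = np.asarray(z, dtype=np.complex128)
    if z.ndim != 2:
        raise ValueError("analytic signal must be 2-D (channels x samples)")
    return _wpli_from_imag(np.ascontiguousarray(z.real),
                           np.ascontiguousarray(z.imag),
                           np.abs(z))


def analytic_band_signal(x: np.ndarray, fs: float, band: Band,
                         trim_s: float = DEFAULT_TRIM_S) -> np.ndarray:
    """Band-pass one epoch and return the edge-trimmed analytic signal."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    nyq = fs / 2
    if band.high >= nyq:
        raise ValueError(f"band {band.name} exceeds Nyquist frequency")
    sos = signal.butter(4, [band.low, band.high], btype="bandpass",
                        fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x, axis=-1)
    z = signal.hilbert(filtered, axis=-1)
    n_trim = int(round(trim_s * fs))
    if 2 * n_trim >= x.shape[-1]:
        raise ValueError("epoch too short for the requested edge trim")
    return z[:, n_trim: x.shape[-1] - n_trim] if n_trim else z


def wpli_epoch(x: np.ndarray, fs: float, band: Band,
               trim_s: float = DEFAULT_TRIM_S) -> np.ndarray:
    """wPLI matrix of one epoch (channels x samples) in one band.

    Constant (zero-variance) channels are assigned 0 against every other
    channel rather than raising.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    flat = np.ptp(x, axis=-1) == 0
    z = analytic_band_signal(x, fs, band, trim_s)
    w = wpli_from_analytic(z)
    if flat.any():
        w[flat, :] = 0.0
        w[:, flat] = 0.0
    return w


def wpli_stack(epochs: EpochSet, bands: BandSet | None = None,
               trim_s: float = DEFAULT_TRIM_S) -> ConnectivityStack:
    """One wPLI matrix per epoch per band; no averaging across epochs."""
    bands = bands or BandSet.default()
    if epochs.n_epochs == 0:
        raise ValueError("empty EpochSet")
    band_list = list(bands)
    n_c = epochs.n_channels
    out = np.zeros((len(band_list), epochs.n_epochs, n_c, n_c))
    flat = np.ptp(epochs.data, axis=-1) == 0  # (epochs, channels)
    n_trim = int(round(trim_s * epochs.fs))
    if 2 * n_trim >= epochs.data.shape[-1]:
        raise ValueError("epoch too short for the requested edge trim")
    for bi, band in enumerate(band_list):
        if band.high >= epochs.fs / 2:
            raise ValueError(f"band {band.name} exceeds Nyquist frequency")
        # filter + Hilbert batched over epochs: same numerics as wpli_epoch
        sos = signal.butter(4, [band.low, band.high], btype="bandpass",
                            fs=epochs.fs, output="sos")
        filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
        z = signal.hilbert(filtered, axis=-1)
        if n_trim:
            z = z[..., n_trim:-n_trim]
        u = np.ascontiguousarray(z.real)
        v = np.ascontiguousarray(z.imag)
        a = np.abs(z)
        for ei in range(epochs.n_epochs):
            w = _wpli_from_imag(u[ei], v[ei], a[ei])
            if flat[ei].any():
                w[flat[ei], :] = 0.0
                w[:, flat[ei]] = 0.0
            out[bi, ei] = w
    provenance = {"trim_s": trim_s,
                  "source": dict(epochs.provenance.get("source_meta", {})),
                  "subject_id": epochs.provenance.get("subject_id", ""),
                  "condition": epochs.provenance.get("condition", "")}
    if flat.any():
        names = epochs.channel_names
        provenance["zero_variance_channels"] = sorted(
            {names[c] for e, c in zip(*np.nonzero(flat))})
    return ConnectivityStack(
        data=out, bands=band_list,
        channel_names=list(epochs.channel_names),
        provenance=provenance,
    )


# --------------------------------------------------------------------------
# surrogate null
# --------------------------------------------------------------------------

def wpli_surrogate_null(epochs: EpochSet, band: Band, n_surrogates: int = 200,
                        seed: int | np.random.SeedSequence = 0,
                        trim_s: float = DEFAULT_TRIM_S) -> np.ndarray:
    """Null distribution of the mean off-diagonal wPLI under phase shuffling.

    Each surrogate independently randomizes the Fourier phases of every
    channel of every epoch (preserving each channel's power spectrum
    while destroying all cross-channel phase relations), recomputes the
    epoch-wise wPLI in ``band``, and records the mean off-diagonal value.
    The 95th percentile of the returned array is the finite-sample noise
    ceiling for "no genuine lagged coupling".
    """
    rng = np.random.default_rng(seed)
    data = epochs.data
    spec = np.fft.rfft(data, axis=-1)
    n = data.shape[-1]
    n_c = epochs.n_channels
    off = ~np.eye(n_c, dtype=bool)
    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        phases = rng.uniform(0, 2 * np.pi, spec.shape)
        phases[..., 0] = 0.0
        if n % 2 == 0:
            phases[..., -1] = 0.0
        surro = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n, axis=-1)
        vals = [wpli_epoch(surro[e], epochs.fs, band, trim_s)[off]
                for e in range(data.shape[0])]
        out[s] = float(np.mean(vals))
    return out


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def normalize_stack(stack: ConnectivityStack,
                    scope: str = "per-band") -> ConnectivityStack:
    """Min-max rescale wPLI values to span [0, 1].

    scope="per-band" (default): one affine map per band, using the
    off-diagonal minimum and maximum pooled over all epochs of that band
    in this subject-by-condition stack.  scope="individual": a single
    map pooled over all epochs *and* bands of the stack.
    scope="per-matrix": each epoch-band matrix is rescaled by its own
    range.  The min/max used are recorded for audit.  Degenerate input
    (max == min) raises.

    Per-band is the default because pooling across bands couples the
    bands' scales: a genuine change confined to one band then shifts the
    affine map applied to every other band of the same recording, which
    can masquerade as a (spurious) condition effect in unaffected bands.
    """
    n = stack.n_channels
    off = ~np.eye(n, dtype=bool)
    data = stack.data.copy()
    if scope == "per-band":
        lows, highs = [], []
        for bi in range(data.shape[0]):
            vals = stack.data[bi][:, off]
            lo, hi = float(vals.min()), float(vals.max())
            if hi <= lo:
                raise ValueError(f"degenerate stack: band {bi} has "
                                 "max wPLI equal to min")
            data[bi][:, off] = (data[bi][:, off] - lo) / (hi - lo)
            lows.append(lo)
            highs.append(hi)
        norm_min, norm_max = min(lows), max(highs)
    elif scope == "individual":
        vals = stack.data[:, :, off]
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            raise ValueError("degenerate stack: max wPLI equals min")
        data[:, :, off] = (data[:, :, off] - lo) / (hi - lo)
        norm_min, norm_max = lo, hi
    elif scope == "per-matrix":
        for bi in range(data.shape[0]):
            for ei in range(data.shape[1]):
                vals = data[bi, ei][off]
                lo, hi = float(vals.min()), float(vals.max())
                if hi <= lo:
                    raise ValueError(
                        f"degenerate matrix (band {bi}, epoch {ei})")
                data[bi, ei][off] = (data[bi, ei][off] - lo) / (hi - lo)
        norm_min = norm_max = None
    else:
        raise ValueError(
            "scope must be 'per-band', 'individual' or 'per-matrix'")
    return ConnectivityStack(
        data=data, bands=list(stack.bands),
        channel_names=list(stack.channel_names),
        norm_scope=scope, norm_min=norm_min, norm_max=norm_max,
        provenance=dict(stack.provenance),
    )
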