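"""On-disk containers for recordings, epoch sets and connectivity stacks.

Each container is a single ``.npz`` archive holding the sample arrays
plus a JSON header with sampling rate, channel names and provenance;
round-trips are bit-exact.  Optional conversion to/from MNE ``Raw``
objects is provided for interoperability with standard EEG formats when
``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .bands import Band, BandSet
from .connectivity import ConnectivityStack
from .containers import EpochSet, Recording


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, BandSet):
        return [[b.name, b.low, b.high] for b in obj]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    return obj


def save_recording(path: str | Path, rec: Recording) -> None:
    header = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "reference": rec.reference,
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "meta": _jsonable(rec.meta),
    }
    np.savez(path, data=rec.data, header=json.dumps(header))


def load_recording(path: str | Path) -> Recording:
    with np.load(path, allow_pickle=False) as f:
        header = json.loads(str(f["header"]))
        return Recording(
            data=f["data"], fs=header["fs"],
            channel_names=header["channel_names"],
            reference=header["reference"],
            subject_id=header["subject_id"], condition=header["condition"],
            meta=header["meta"],
        )


def save_epochs(path: str | Path, es: EpochSet) -> None:
    header = {
        "fs": es.fs,
        "channel_names": es.channel_names,
        "provenance": _jsonable(es.provenance),
    }
    np.savez(path, data=es.data, header=json.dumps(header))


def load_epochs(path: str | Path) -> EpochSet:
    with np.load(path, allow_pickle=False) as f:
        header = json.loads(str(f["header"]))
        return EpochSet(
            data=f["data"], fs=header["fs"],
            channel_names=header["channel_names"],
            provenance=header["provenance"],
        )


def save_stack(path: str | Path, stack: ConnectivityStack) -> None:
    header = {
        "bands": [[b.name, b.low, b.high] for b in stack.bands],
        "channel_names": stack.channel_names,
        "norm_scope": stack.norm_scope,
        "norm_min": stack.norm_min,
        "norm_max": stack.norm_max,
        "provenance": _jsonable(stack.provenance),
    }
    np.savez(path, data=stack.data, header=json.dumps(header))


def load_stack(path: str | Path) -> ConnectivityStack:
    with np.load(path, allow_pickle=False) as f:
        header = json.loads(str(f["header"]))
        return ConnectivityStack(
            data=f["data"],
            bands=[Band(n, lo, hi) for n, lo, hi in header["bands"]],
            channel_names=header["channel_names"],
            norm_scope=header["norm_scope"],
            norm_min=header["norm_min"], norm_max=header["norm_max"],
            provenance=header["provenance"],
        )


# --------------------------------------------------------------------------
# optional MNE interoperability
# --------------------------------------------------------------------------

def recording_from_mne(raw: Any, subject_id: str = "",
                       condition: str = "") -> Recording:
    """Convert an ``mne.io.Raw`` (any format MNE can read) to a Recording."""
    data = raw.get_data() * 1e6  # MNE stores volts; we use microvolts
    return Recording(
        data=data, fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        reference="common-average",
        subject_id=subject_id, condition=condition,
        meta={"imported_from": "mne"},
    )


def recording_to_mne(rec: Recording) -> Any:
    """Convert a Recording to an ``mne.io.RawArray`` (requires mne)."""
    import mne

    info = mne.create_info(rec.channel_names, rec.fs, ch_types="eeg")
    return mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
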