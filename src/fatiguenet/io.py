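"""On-disk formats: internal .npz container and EDF reading.

The internal container is a compressed NumPy archive holding the
channels x time matrix under ``data`` plus a JSON metadata string
(rate, channel names, optional state/subject).  EDF files are read
through MNE and converted to microvolts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .errors import FormatError
from .preprocess import EEGRecording

__all__ = [
    "save_recording",
    "load_recording",
    "read_recording",
    "read_edf",
    "save_features",
    "sha256_of",
]


def save_recording(
    path,
    rec: EEGRecording,
    state: str | None = None,
    subject_id: str | None = None,
) -> Path:
    """Write a recording (+ optional labels) to the internal container."""
    path = Path(path)
    meta = {
        "rate": rec.rate,
        "channel_names": rec.channel_names,
        "state": state,
        "subject_id": subject_id,
        "units": "uV",
    }
    np.savez_compressed(path, data=rec.data, meta=np.array(json.dumps(meta)))
    # np.savez appends .npz when missing
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_recording(path) -> tuple[EEGRecording, dict]:
    """Read the internal container; returns (recording, metadata)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    try:
        with np.load(path, allow_pickle=False) as z:
            if "data" not in z or "meta" not in z:
                raise FormatError(f"{path}: missing 'data' or 'meta' entry")
            data = z["data"]
            meta = json.loads(str(z["meta"]))
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not a readable container ({exc})") from exc
    if "rate" not in meta or "channel_names" not in meta:
        raise FormatError(f"{path}: metadata lacks rate/channel_names")
    rec = EEGRecording(data=data, rate=float(meta["rate"]),
                       channel_names=list(meta["channel_names"]))
    return rec, meta


def read_edf(path) -> EEGRecording:
    """Read an EDF file (values converted volts -> microvolts)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    try:
        import mne

        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse as EDF ({exc})") from exc
    return EEGRecording(
        data=raw.get_data() * 1e6,
        rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
    )


def read_recording(path, format: str = "auto") -> EEGRecording:
    """Dispatch on ``format`` or the file extension (.npz / .edf)."""
    path = Path(path)
    if format == "auto":
        ext = path.suffix.lower()
        if ext == ".npz":
            format = "internal"
        elif ext == ".edf":
            format = "edf"
        else:
            raise FormatError(f"cannot infer format from extension {ext!r}")
    if format == "internal":
        return load_recording(path)[0]
    if format == "edf":
        return read_edf(path)
    raise FormatError(f"unknown format {format!r}")


def save_features(path, features: np.ndarray, labels=None,
                  feature_names=None, subject_ids=None) -> Path:
    """Write a samples x features matrix as CSV with optional columns."""
    import pandas as pd

    path = Path(path)
    features = np.asarray(features)
    cols = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i}" for i in range(features.shape[1])]
    )
    df = pd.DataFrame(features, columns=cols)
    if labels is not None:
        df.insert(0, "label", list(labels))
    if subject_ids is not None:
        df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
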