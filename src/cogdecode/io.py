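"""Readers and writers.

The exchange layout ``{data, labels, fs, channel_names, t0_ms}`` is the
native on-disk format (NPZ or HDF5, little-endian float64).  EEGLAB ``.set``
epoch files are read through scipy's MAT loader; EDF and FIF require the
optional :mod:`mne` dependency.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .features import FeatureDescriptor, FeatureMatrix
from .signal_model import EpochSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "read_epochs",
    "save_feature_matrix_tsv",
    "load_feature_matrix_tsv",
    "save_feature_matrix_hdf5",
    "load_feature_matrix_hdf5",
]


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Write the exchange layout as .npz or .h5 (by extension)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            data=epochs.data.astype("<f8"),
            labels=epochs.labels,
            fs=epochs.fs,
            channel_names=np.array(epochs.channel_names),
            t0_ms=epochs.t0_ms,
        )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=epochs.data.astype("<f8"))
            f.create_dataset("labels", data=epochs.labels)
            f.attrs["fs"] = epochs.fs
            f.attrs["t0_ms"] = epochs.t0_ms
            f.create_dataset(
                "channel_names",
                data=np.array(epochs.channel_names, dtype=h5py.string_dtype()),
            )
    else:
        raise ValueError(f"unsupported epoch format {path.suffix!r}")


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return EpochSet(
                data=z["data"],
                labels=z["labels"],
                fs=float(z["fs"]),
                channel_names=[str(c) for c in z["channel_names"]],
                t0_ms=float(z["t0_ms"]),
            )
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return EpochSet(
                data=f["data"][()],
                labels=f["labels"][()],
                fs=float(f.attrs["fs"]),
                channel_names=[
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in f["channel_names"][()]
                ],
                t0_ms=float(f.attrs["t0_ms"]),
            )
    raise ValueError(f"unsupported epoch format {path.suffix!r}")


def _read_eeglab_set(path: Path) -> EpochSet:
    from scipy.io import loadmat

    m = loadmat(str(path), squeeze_me=True, struct_as_record=False)
    eeg = m["EEG"] if "EEG" in m else m[[k for k in m if not k.startswith("_")][0]]
    data = np.asarray(eeg.data, dtype=float)
    if data.ndim != 3:
        raise ValueError(".set file does not contain epoched (3-D) data")
    # EEGLAB stores channels x samples x trials
    data = np.transpose(data, (2, 0, 1))
    chlocs = np.atleast_1d(eeg.chanlocs)
    names = [str(c.labels) for c in chlocs]
    events = np.atleast_1d(eeg.epoch)
    labels = []
    for ep in events:
        t = ep.eventtype
        t = t[0] if isinstance(t, (list, np.ndarray)) else t
        labels.append(t)
    return EpochSet(
        data=data,
        labels=np.asarray(labels),
        fs=float(eeg.srate),
        channel_names=names,
        t0_ms=float(eeg.xmin) * 1000.0,
    )


def read_epochs(path: str | Path) -> EpochSet:
    """Dispatch on extension: .npz/.h5 exchange, .set, .fif, .edf."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".npz", ".h5", ".hdf5"):
        return load_epochs(path)
    if suffix == ".set":
        return _read_eeglab_set(path)
    if suffix in (".fif", ".edf"):
        try:
            import mne
        except ImportError as err:
            raise ImportError(
                f"reading {suffix} requires the optional 'mne' dependency "
                "(pip install cogdecode[readers])"
            ) from err
        if suffix == ".fif":
            ep = mne.read_epochs(str(path), preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
            ep = mne.make_fixed_length_epochs(raw, preload=True, verbose="error")
        data = ep.get_data() * 1e6  # volts -> microvolts
        labels = ep.events[:, 2]
        return EpochSet(
            data=data,
            labels=labels,
            fs=float(ep.info["sfreq"]),
            channel_names=list(ep.ch_names),
            t0_ms=float(ep.times[0]) * 1000.0,
        )
    raise ValueError(f"unrecognized epoch file format {suffix!r}")


# ---------------------------------------------------------------------------
# feature matrices


def _descriptor_header(d: FeatureDescriptor) -> str:
    coef = "" if d.coef is None else str(d.coef)
    return f"{d.family};{d.band};{d.window};{d.locus};{coef}"


def _descriptor_from_header(s: str) -> FeatureDescriptor:
    family, band, window, locus, coef = s.split(";")
    return FeatureDescriptor(
        family=family,
        band=band,
        window=int(window),
        locus=locus,
        coef=int(coef) if coef else None,
    )


def save_feature_matrix_tsv(path: str | Path, fm: FeatureMatrix) -> None:
    """TSV with a descriptor header line; first column is the trial label."""
    labels = fm.labels if fm.labels is not None else np.zeros(len(fm.X), dtype=int)
    header = "label\t" + "\t".join(_descriptor_header(d) for d in fm.descriptors)
    body = np.column_stack([np.asarray(labels, dtype=float), fm.X])
    np.savetxt(path, body, delimiter="\t", header=header, comments="")


def load_feature_matrix_tsv(path: str | Path) -> FeatureMatrix:
    with open(path) as f:
        header = f.readline().rstrip("\n").split("\t")
    body = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    desc = [_descriptor_from_header(h) for h in header[1:]]
    return FeatureMatrix(
        X=body[:, 1:], descriptors=desc, labels=body[:, 0].astype(int)
    )


def save_feature_matrix_hdf5(path: str | Path, fm: FeatureMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=fm.X.astype("<f8"))
        if fm.labels is not None:
            f.create_dataset("labels", data=fm.labels)
        st = h5py.string_dtype()
        f.create_dataset(
            "descriptors",
            data=np.array([_descriptor_header(d) for d in fm.descriptors], dtype=st),
        )


def load_feature_matrix_hdf5(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        desc = [
            _descriptor_from_header(s.decode() if isinstance(s, bytes) else s)
            for s in f["descriptors"][()]
        ]
        labels = f["labels"][()] if "labels" in f else None
        return FeatureMatrix(X=f["X"][()], descriptors=desc, labels=labels)


def save_report_json(path: str | Path, report_dict: dict) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2, sort_keys=True))
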