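"""Epoched-EEG data model and its single-file HDF5 container.

The central object is :class:`EEGEpochs`: a ``(n_trials, n_channels,
n_samples)`` tensor of labelled trials with a sampling rate and an ordered
channel list.  All downstream stages consume and produce this object, and
every matrix row index throughout the package refers to the channel order
stored here (row ``c`` = channel ``c``, 0-based).

Container schema (HDF5, one file):

====================  =========================================
dataset ``data``      float64, ``(n_trials, n_channels, n_samples)``
dataset ``labels``    int64, ``(n_trials,)``
dataset ``channel_names``  UTF-8 strings, ``(n_channels,)``
file attribute ``fs``  scalar sampling rate in Hz
====================  =========================================

Labels are stored exactly as given; the canonical mapping "smaller label ->
condition 1" is applied at fit time, so files produced by other tools need
no relabelling.  A plain-CSV fixture dialect (one header-free matrix per
trial, channels as rows) is supported for small test data.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .exceptions import FormatError, ValidationError

__all__ = [
    "EEGEpochs",
    "ContinuousEEG",
    "write_epochs",
    "read_epochs",
    "write_epochs_csv",
    "read_epochs_csv",
    "from_mne_raw",
]


@dataclass
class EEGEpochs:
    """Labelled epoched EEG: trials x channels x samples plus metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial tensor; amplitude units are treated as opaque (typically uV).
    labels : ndarray of int, shape (n_trials,)
        Condition label per trial; at most two distinct values.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_names : list of str
        Ordered channel names; ``len == n_channels``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data: expected 3-D (trials, channels, samples), got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data: contains non-finite values")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.issubdtype(self.labels.dtype, np.floating) and np.all(
                self.labels == np.round(self.labels)
            ):
                self.labels = self.labels.astype(np.int64)
            else:
                raise ValidationError("labels: must be integers")
        self.labels = self.labels.astype(np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise ValidationError(
                f"labels: length {self.labels.shape} does not match "
                f"n_trials {self.data.shape[0]}"
            )
        if len(np.unique(self.labels)) > 2:
            raise ValidationError("labels: more than two distinct values")
        if not (np.isscalar(self.fs) or np.ndim(self.fs) == 0) or not self.fs > 0:
            raise ValidationError(f"fs: must be a positive scalar, got {self.fs!r}")
        self.fs = float(self.fs)
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValidationError(
                f"channel_names: length {len(self.channel_names)} does not match "
                f"n_channels {self.data.shape[1]}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EEGEpochs":
        """Return a new object restricted to the given trial indices."""
        idx = np.asarray(idx)
        return EEGEpochs(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, EEGEpochs):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.channel_names == other.channel_names
        )


@dataclass
class ContinuousEEG:
    """Un-segmented multichannel recording: channels x samples."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(
                f"data: expected 2-D (channels, samples), got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data: contains non-finite values")
        if not self.fs > 0:
            raise ValidationError(f"fs: must be positive, got {self.fs!r}")
        self.fs = float(self.fs)
        self.channel_names = [str(c) for c in self.channel_names]
        if self.channel_names and len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"channel_names: length {len(self.channel_names)} does not match "
                f"n_channels {self.data.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def write_epochs(epochs: EEGEpochs, path) -> None:
    """Write an :class:`EEGEpochs` object to the HDF5 container at *path*.

    The object is validated before any file is created; the numeric payload
    round-trips bit-exactly through :func:`read_epochs`.
    """
    if not isinstance(epochs, EEGEpochs):
        raise ValidationError("epochs: expected an EEGEpochs instance")
    # construction already validated; re-check the tensor in case of mutation
    if not np.all(np.isfinite(epochs.data)):
        raise ValidationError("data: contains non-finite values")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("labels", data=epochs.labels, track_times=False)
        f.create_dataset(
            "channel_names",
            data=np.array(epochs.channel_names, dtype=h5py.string_dtype("utf-8")),
            track_times=False,
        )
        f.attrs["fs"] = epochs.fs


def read_epochs(path) -> EEGEpochs:
    """Read and validate an epoch container written by :func:`write_epochs`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        for name in ("data", "labels", "channel_names"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '{name}'")
        if "fs" not in f.attrs:
            raise FormatError(f"{path}: missing file attribute 'fs'")
        data = f["data"][()]
        labels = f["labels"][()]
        names = [
            c.decode("utf-8") if isinstance(c, bytes) else str(c)
            for c in f["channel_names"][()]
        ]
        fs = float(f.attrs["fs"])
    if np.ndim(data) != 3:
        raise FormatError(f"{path}: dataset 'data' is not 3-D")
    try:
        return EEGEpochs(data=data, labels=labels, fs=fs, channel_names=names)
    except ValidationError as e:
        raise FormatError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# CSV fixture dialect: a directory holding trial_<i>.csv (channels as rows,
# comma-separated, no header), labels.csv (one integer per line) and meta.csv
# with rows "fs,<Hz>" and "channels,<name>,<name>,...".
# ---------------------------------------------------------------------------


def write_epochs_csv(epochs: EEGEpochs, directory) -> None:
    """Write the CSV-fixture twin of the HDF5 container."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(epochs.n_trials):
        np.savetxt(directory / f"trial_{i}.csv", epochs.data[i], delimiter=",")
    np.savetxt(directory / "labels.csv", epochs.labels, fmt="%d")
    with open(directory / "meta.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fs", repr(epochs.fs)])
        w.writerow(["channels", *epochs.channel_names])


def read_epochs_csv(directory) -> EEGEpochs:
    """Load a CSV fixture directory into the same object as its HDF5 twin."""
    directory = Path(directory)
    meta_path = directory / "meta.csv"
    if not meta_path.exists():
        raise FormatError(f"{directory}: missing meta.csv")
    fs = None
    names: list[str] = []
    with open(meta_path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            if row[0] == "fs":
                fs = float(row[1])
            elif row[0] == "channels":
                names = row[1:]
    if fs is None:
        raise FormatError(f"{meta_path}: missing 'fs' row")
    labels_path = directory / "labels.csv"
    if not labels_path.exists():
        raise FormatError(f"{directory}: missing labels.csv")
    labels = np.atleast_1d(np.loadtxt(labels_path, dtype=np.int64, ndmin=1))
    trial_files = sorted(
        directory.glob("trial_*.csv"),
        key=lambda p: int(re.search(r"trial_(\d+)", p.name).group(1)),
    )
    if len(trial_files) != len(labels):
        raise FormatError(
            f"{directory}: {len(trial_files)} trial files but {len(labels)} labels"
        )
    trials = [np.atleast_2d(np.loadtxt(p, delimiter=",")) for p in trial_files]
    data = np.stack(trials, axis=0)
    return EEGEpochs(data=data, labels=labels, fs=fs, channel_names=names)


def from_mne_raw(raw, events) -> tuple[ContinuousEEG, list[tuple[int, int]]]:
    """Adapter hook for continuous recordings loaded with MNE (EDF/GDF).

    Accepts any object exposing ``get_data()``, ``info['sfreq']`` and
    ``ch_names`` (duck-typed, so MNE is not a hard dependency) together with
    an MNE-style ``(n_events, 3)`` array of ``(onset_sample, _, code)`` rows.
    Returns a :class:`ContinuousEEG` and a list of ``(onset, code)`` pairs
    for :func:`ccssp.preprocessing.segment`.
    """
    data = np.asarray(raw.get_data(), dtype=np.float64)
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    cont = ContinuousEEG(data=data, fs=fs, channel_names=names)
    events = np.asarray(events)
    table = [(int(r[0]), int(r[-1])) for r in events]
    return cont, table
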