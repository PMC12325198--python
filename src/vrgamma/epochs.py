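"""Epoched-EEG container and file I/O.

An :class:`EpochSet` holds one subject's epoched recording as a
``trials x channels x samples`` tensor in microvolts, together with the
sampling rate, the epoch start relative to stimulus onset, per-trial
valence labels and the post-rejection keep mask.

On disk an epoch store is a small HDF5 file::

    /data      float32, (trials, channels, samples), microvolts
    /labels    variable-length UTF-8 strings, (trials,)
    /kept      bool, (trials,)
    /channels  variable-length UTF-8 strings, (channels,)
    attrs      fs (Hz), t0_ms, subject_id

Feature tables (one row per kept trial, one column per named feature,
plus ``subject`` and ``label`` bookkeeping columns) are thin wrappers
around a pandas DataFrame and round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .montage import Montage

__all__ = ["EpochSet", "FeatureTable", "save_epochs", "load_epochs"]

VALENCES = ("positive", "negative", "neutral")


@dataclass
class EpochSet:
    """Subject-tagged tensor of epoched EEG trials.

    ``data`` is ``(trials, channels, samples)`` in microvolts. ``t0_ms``
    is the epoch start relative to stimulus onset (-1000 for the standard
    design, so sample ``-t0_ms/1000*fs`` is the stimulus-onset sample).
    """

    subject_id: str
    fs: float
    t0_ms: float
    data: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.n_trials, dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if len(self.labels) != self.n_trials or len(self.kept_mask) != self.n_trials:
            raise ValueError("labels/kept_mask length must equal number of trials")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        unknown = set(self.labels) - set(VALENCES)
        if unknown:
            raise ValueError(f"unknown valence labels: {sorted(unknown)}")

    # -- shape helpers -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample time axis in ms relative to stimulus onset."""
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def sample_at(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (start-inclusive convention)."""
        return int(round((t_ms - self.t0_ms) * self.fs / 1000.0))

    def with_data(self, data: np.ndarray) -> "EpochSet":
        """Copy of this set with ``data`` replaced (labels/mask shared)."""
        return replace(self, data=data, kept_mask=self.kept_mask.copy())

    def kept(self) -> "EpochSet":
        """Restriction to kept trials only."""
        m = self.kept_mask
        return replace(self, data=self.data[m], labels=self.labels[m],
                       kept_mask=np.ones(int(m.sum()), dtype=bool))


def save_epochs(epochs: EpochSet, path) -> None:
    """Write an epoch store in the documented HDF5 layout (float32 data)."""
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data.astype(np.float32))
        fh.create_dataset("labels", data=np.array(list(epochs.labels), dtype=str_dt))
        fh.create_dataset("kept", data=epochs.kept_mask)
        fh.create_dataset("channels", data=np.array(list(epochs.channel_names), dtype=str_dt))
        fh.attrs["fs"] = float(epochs.fs)
        fh.attrs["t0_ms"] = float(epochs.t0_ms)
        fh.attrs["subject_id"] = epochs.subject_id


def load_epochs(path, montage: Montage, expected_fs: float | None = None) -> EpochSet:
    """Load an epoch store, coercing channel order to the montage order.

    Raises
    ------
    ValueError
        If channels required by the montage are absent (all missing names
        are listed) or the stored sampling rate contradicts ``expected_fs``.
    """
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        labels = [s.decode() if isinstance(s, bytes) else s for s in fh["labels"][()]]
        kept = fh["kept"][()].astype(bool)
        channels = [s.decode() if isinstance(s, bytes) else s for s in fh["channels"][()]]
        fs = float(fh.attrs["fs"])
        t0_ms = float(fh.attrs["t0_ms"])
        subject_id = str(fh.attrs["subject_id"])
    if expected_fs is not None and fs != expected_fs:
        raise ValueError(f"sampling rate mismatch: file has {fs} Hz, expected {expected_fs} Hz")
    missing = [c for c in montage.channel_names if c not in channels]
    if missing:
        raise ValueError(f"epoch store is missing montage channels: {missing}")
    order = [channels.index(c) for c in montage.channel_names]
    return EpochSet(subject_id=subject_id, fs=fs, t0_ms=t0_ms,
                    data=data[:, order, :], labels=np.array(labels, dtype=object),
                    channel_names=montage.channel_names, kept_mask=kept)


@dataclass
class FeatureTable:
    """Trials-by-features matrix with per-row subject and valence label.

    The underlying frame carries one column per feature plus ``subject``
    and ``label``. Feature columns must be unique and free of missing
    values; labels are restricted to the binary positive/negative
    contrast used by the classifiers.
    """

    frame: pd.DataFrame

    RESERVED = ("subject", "label")

    def __post_init__(self) -> None:
        for col in self.RESERVED:
            if col not in self.frame.columns:
                raise ValueError(f"feature table needs a {col!r} column")
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature columns: {dupes}")
        if self.frame[self.feature_names].isna().any().any():
            raise ValueError("feature table contains missing values")
        bad = set(self.frame["label"]) - {"positive", "negative"}
        if bad:
            raise ValueError(f"feature-table labels must be positive/negative, got {sorted(bad)}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.RESERVED]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def features(self, names: list[str] | None = None) -> np.ndarray:
        return self.frame[names or self.feature_names].to_numpy(dtype=float)

    def labels01(self) -> np.ndarray:
        """Labels encoded 0 = negative, 1 = positive."""
        return (self.frame["label"] == "positive").to_numpy(dtype=int)

    def subjects(self) -> np.ndarray:
        return self.frame["subject"].to_numpy()

    def select_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureTable(self.frame[list(names) + list(self.RESERVED)].copy())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path))
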