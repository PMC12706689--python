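"""Epoched multichannel EEG container and on-disk formats.

An :class:`EpochSet` holds one subject-condition block of cleaned, epoched
signal as an ``epochs x channels x samples`` array, together with the
sampling rate and ordered 10-20 channel labels.  HDF5 is the canonical
interchange format (datasets ``/data`` and ``/labels``, scalar attributes
``srate``, ``condition``, ``subject_id``); CSV (one file per epoch, channels
as columns) is supported for small desk-scale fixtures.  BrainVision and EDF
recordings can be imported through :mod:`mne` and re-sliced into fixed-length
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet", "read_epochs", "write_epochs"]


@dataclass
class EpochSet:
    """One subject-condition block of epoched multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Real-valued signal.  For freshly segmented (undifferenced) data
        ``n_samples == round(srate * epoch_duration)``.
    srate : float
        Sampling rate in Hz.
    channel_labels : list of str
        Ordered, unique channel names (10-20 convention).
    subject_id : str
    condition : str
        Cue condition label, conventionally ``"lexical"`` or ``"color"``.
    epoch_duration : float
        Nominal epoch length in seconds at segmentation time.
    """

    data: np.ndarray
    srate: float = 500.0
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "S00"
    condition: str = "lexical"
    epoch_duration: float = 4.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (epochs x channels x samples), got ndim={self.data.ndim}"
            )
        n_ch = self.data.shape[1]
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(n_ch)]
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if self.srate <= 0:
            raise ValueError("srate must be positive")

    # -- basic introspection -------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None

    def copy_with(self, **changes) -> "EpochSet":
        """Return a shallow-copied EpochSet with selected fields replaced."""
        out = replace(self, **changes)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<EpochSet {self.subject_id}/{self.condition}: "
            f"{self.n_epochs} epochs x {self.n_channels} ch x {self.n_samples} samples "
            f"@ {self.srate:g} Hz>"
        )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path: str | Path, format: str = "hdf5") -> Path:
    """Serialize an EpochSet.

    ``hdf5`` writes a single file; ``csv`` writes one ``<stem>_epochNNN.csv``
    per epoch with channels as columns.
    """
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=epochs.data)
            f.create_dataset(
                "labels", data=np.array(epochs.channel_labels, dtype="S")
            )
            f.attrs["srate"] = epochs.srate
            f.attrs["condition"] = epochs.condition
            f.attrs["subject_id"] = epochs.subject_id
            f.attrs["epoch_duration"] = epochs.epoch_duration
        return path
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for i in range(epochs.n_epochs):
            df = pd.DataFrame(epochs.data[i].T, columns=epochs.channel_labels)
            df.to_csv(path / f"epoch{i:03d}.csv", index=False)
        return path
    raise ValueError(f"unknown format {format!r}")


def _read_hdf5(path: Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"])
        labels = [lab.decode() for lab in f["labels"][()]]
        return EpochSet(
            data=data,
            srate=float(f.attrs["srate"]),
            channel_labels=labels,
            subject_id=str(f.attrs.get("subject_id", "S00")),
            condition=str(f.attrs.get("condition", "lexical")),
            epoch_duration=float(f.attrs.get("epoch_duration", 4.0)),
        )


def _read_csv_dir(path: Path, srate: float, channel_labels: list[str] | None) -> EpochSet:
    files = sorted(path.glob("epoch*.csv"))
    if not files:
        raise FileNotFoundError(f"no epoch*.csv files under {path}")
    mats = []
    labels = channel_labels
    for fp in files:
        df = pd.read_csv(fp)
        if labels is None:
            labels = list(df.columns)
        missing = [c for c in labels if c not in df.columns]
        if missing:
            raise ValueError(f"{fp.name}: missing channel column(s) {missing}")
        mats.append(df[labels].to_numpy().T)
    return EpochSet(np.stack(mats), srate=srate, channel_labels=list(labels))


def _read_mne(path: Path, fmt: str, srate: float | None,
              epoch_duration: float) -> EpochSet:
    # delegated import of binary vendor formats; re-sliced into fixed epochs
    import mne

    if fmt == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    if srate is not None and abs(fs - srate) > 1e-9:
        raise ValueError(f"recording srate {fs} Hz != configured {srate} Hz")
    sig = raw.get_data()
    step = int(round(fs * epoch_duration))
    n_ep = sig.shape[1] // step
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")
    data = sig[:, : n_ep * step].reshape(sig.shape[0], n_ep, step).transpose(1, 0, 2)
    return EpochSet(data, srate=fs, channel_labels=list(raw.ch_names),
                    epoch_duration=epoch_duration)


def read_epochs(
    path: str | Path,
    format: str = "hdf5",
    srate: float | None = None,
    channel_labels: list[str] | None = None,
    epoch_duration: float = 4.0,
) -> EpochSet:
    """Load an EpochSet from ``hdf5``, ``csv``, ``brainvision`` or ``edf``.

    When ``srate`` / ``channel_labels`` are given they are validated against
    the file and a mismatch raises ``ValueError``.
    """
    path = Path(path)
    if format == "hdf5":
        es = _read_hdf5(path)
    elif format == "csv":
        if srate is None:
            raise ValueError("csv import requires an explicit srate")
        es = _read_csv_dir(path, srate, channel_labels)
    elif format in ("brainvision", "edf"):
        es = _read_mne(path, format, srate, epoch_duration)
    else:
        raise ValueError(f"unknown format {format!r}")

    if srate is not None and abs(es.srate - srate) > 1e-9:
        raise ValueError(f"srate mismatch: file {es.srate}, expected {srate}")
    if channel_labels is not None:
        missing = [c for c in channel_labels if c not in es.channel_labels]
        if missing:
            raise ValueError(f"missing channel(s): {missing}")
    return es
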