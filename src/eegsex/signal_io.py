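"""Recording I/O, filtering and epoching for multichannel EEG.

A :class:`Recording` is one subject's continuous multichannel signal
(channels x samples) with its sampling rate, 10-20 channel names and sex
label.  The preprocessing chain mirrors standard resting-state practice:
a 50 Hz power-line notch, a 0.15-45 Hz band-pass, retention of the final
analysis segment, and segmentation into non-overlapping fixed-length
epochs (:class:`EpochSet`), the unit of classification downstream.

Two on-disk formats are supported: European Data Format (EDF, read via
mne) and a plain delimited matrix (rows = channels, columns = samples)
with a JSON sidecar carrying ``subject_id``, ``sex``, ``fs`` and
``channels``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .exceptions import ValidationError

log = logging.getLogger(__name__)

SEXES = ("male", "female")

#: 10-20 labels of the 30 effective channels of a 32-electrode cap
#: (A1/A2 mastoid references excluded), anterior to posterior.
CHANNELS_1020_30 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
]


@dataclass
class Recording:
    """One subject's continuous multichannel EEG signal.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    sex : {"male", "female"}
        Subject sex label (the classification target).
    fs : float
        Sampling rate in Hz, > 0.
    channels : list of str
        Ordered, unique channel names (10-20 labels).
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix; all samples finite.
    """

    subject_id: str
    sex: str
    fs: float
    channels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channels = list(self.channels)
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.fs > 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValidationError("data must be a 2-D channels x samples matrix")
        if len(self.channels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel names but {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows cut from one or more recordings.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch); each
    epoch carries its source subject id and sex label.
    """

    epochs: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray
    epoch_len_s: float
    fs: float
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be 3-D (n_epochs, n_channels, n_samples)")
        n = self.epochs.shape[0]
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValidationError("subject_ids and labels must have length n_epochs")
        expected = round(self.epoch_len_s * self.fs)
        if n and self.epochs.shape[2] != expected:
            raise ValidationError(
                f"epoch length {self.epochs.shape[2]} != round(epoch_len_s*fs) = {expected}"
            )
        if self.channels and len(self.channels) != self.epochs.shape[1]:
            raise ValidationError("channel name count != epoch channel axis")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @classmethod
    def concatenate(cls, sets: list["EpochSet"]) -> "EpochSet":
        """Stack epoch sets from several recordings (same geometry required)."""
        if not sets:
            raise ValidationError("cannot concatenate an empty list of EpochSets")
        first = sets[0]
        for s in sets[1:]:
            if s.fs != first.fs or s.epoch_len_s != first.epoch_len_s \
                    or s.channels != first.channels:
                raise ValidationError("EpochSets differ in fs/epoch length/channels")
        return cls(
            epochs=np.concatenate([s.epochs for s in sets], axis=0),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            epoch_len_s=first.epoch_len_s,
            fs=first.fs,
            channels=first.channels,
        )


# ---------------------------------------------------------------------------
# I/O

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _sniff_delimiter(path: Path) -> str | None:
    first = path.open("r", encoding="utf-8").readline()
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return None  # any whitespace


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a :class:`Recording` from disk.

    ``format`` is ``"edf"`` or ``"delimited"``; when omitted it is inferred
    from the file extension (``.edf`` -> EDF, anything else -> delimited).
    Delimited files require a JSON sidecar ``<stem>.json`` with keys
    ``subject_id``, ``sex``, ``fs`` and ``channels``; for EDF a sidecar is
    optional and overrides header metadata when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValidationError(f"unknown recording format {format!r}")


def _load_sidecar(path: Path, required: bool) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        if required:
            raise ValidationError(f"missing metadata sidecar {sc}")
        return {}
    meta = json.loads(sc.read_text(encoding="utf-8"))
    if required:
        for key in ("subject_id", "sex", "fs", "channels"):
            if key not in meta:
                raise ValidationError(f"sidecar {sc} is missing required field {key!r}")
    return meta


def _read_delimited(path: Path) -> Recording:
    meta = _load_sidecar(path, required=True)
    data = np.loadtxt(path, delimiter=_sniff_delimiter(path), ndmin=2)
    return Recording(
        subject_id=str(meta["subject_id"]),
        sex=str(meta["sex"]),
        fs=float(meta["fs"]),
        channels=list(meta["channels"]),
        data=data,
    )


def _read_edf(path: Path) -> Recording:
    import mne  # deferred: heavy import only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    meta = _load_sidecar(path, required=False)
    subject_id = str(meta.get("subject_id", path.stem))
    sex = meta.get("sex")
    if sex is None:
        info = raw.info.get("subject_info") or {}
        # EDF sex code: 1 = male, 2 = female
        sex = {1: "male", 2: "female"}.get(info.get("sex"))
        if "his_id" in info:
            subject_id = str(meta.get("subject_id", info["his_id"]))
    if sex is None:
        raise ValidationError(
            f"sex label not present in EDF header of {path}; provide a JSON sidecar"
        )
    return Recording(
        subject_id=subject_id,
        sex=str(sex),
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        data=raw.get_data(),
    )


def write_recording(rec: Recording, path: str | Path, delimiter: str = ",") -> Path:
    """Write a recording as a delimited matrix plus JSON sidecar.

    Returns the data file path; the sidecar lands at ``<stem>.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, rec.data, delimiter=delimiter, fmt="%.10g")
    meta = {
        "subject_id": rec.subject_id,
        "sex": rec.sex,
        "fs": rec.fs,
        "channels": rec.channels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Filtering

def apply_notch(rec: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at ``freq`` Hz (quality factor ``q``).

    Applied forward-backward (``filtfilt``) so epoch alignment is preserved.
    """
    if not 0 < freq < rec.fs / 2:
        raise ValidationError(
            f"notch frequency {freq} Hz outside (0, fs/2) for fs = {rec.fs}"
        )
    b, a = sps.iirnotch(freq, q, fs=rec.fs)
    log.debug("notch filter: %g Hz, Q=%g, fs=%g", freq, q, rec.fs)
    return replace(rec, data=sps.filtfilt(b, a, rec.data, axis=1))


def apply_bandpass(
    rec: Recording, low: float = 0.15, high: float = 45.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (default 0.15-45 Hz, 4th order)."""
    if not 0 < low < high < rec.fs / 2:
        raise ValidationError(
            f"band edges ({low}, {high}) must satisfy 0 < low < high < fs/2 = {rec.fs / 2}"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    log.debug("band-pass: %g-%g Hz order %d, fs=%g", low, high, order, rec.fs)
    return replace(rec, data=sps.sosfiltfilt(sos, rec.data, axis=1))


# ---------------------------------------------------------------------------
# Segment retention and epoching

def retain_final_segment(rec: Recording, duration_s: float = 300.0) -> Recording:
    """Keep the trailing ``duration_s`` seconds (the settled analysis segment)."""
    n = round(duration_s * rec.fs)
    if rec.n_samples < n:
        raise ValidationError(
            f"recording of {rec.duration_s:.1f} s shorter than requested {duration_s} s"
        )
    return replace(rec, data=rec.data[:, rec.n_samples - n:])


def segment_epochs(rec: Recording, epoch_len_s: float = 1.0) -> EpochSet:
    """Cut the recording into consecutive non-overlapping epochs.

    The trailing partial window is discarded; every epoch inherits the
    recording's subject id and sex label.  Epochs shorter than 10 samples
    are rejected (entropy estimators need a minimum series length).
    """
    n_per = round(epoch_len_s * rec.fs)
    if n_per < 10:
        raise ValidationError(
            f"epoch of {n_per} samples too short (need >= 10 for entropy estimation)"
        )
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        log.warning(
            "recording %s (%d samples) shorter than one epoch (%d samples): 0 epochs",
            rec.subject_id, rec.n_samples, n_per,
        )
    discarded = rec.n_samples - n_epochs * n_per
    if discarded:
        log.debug("discarding %d trailing samples of %s", discarded, rec.subject_id)
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs,
        subject_ids=np.full(n_epochs, rec.subject_id, dtype=object),
        labels=np.full(n_epochs, rec.sex, dtype=object),
        epoch_len_s=epoch_len_s,
        fs=rec.fs,
        channels=list(rec.channels),
    )
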