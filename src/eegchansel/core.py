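"""Recordings, I/O, resampling and epoching for two-state EEG data.

The data model mirrors a typical fatigue-driving acquisition: one resting
("JX", label 0) and one fatigued ("ZD", label 1) continuous recording per
subject, a 30-electrode 10-20 montage, and non-overlapping 1-second epochs
as the unit of classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .errors import (
    ConfigError,
    DataError,
    DataQualityError,
    EmptyEpochsError,
    MontageMismatchError,
    UpsamplingError,
)
from .montage import Montage, REFERENCE_LABELS

#: class labels: JX = resting, ZD = fatigued
LABEL_JX = 0
LABEL_ZD = 1


@dataclass
class Recording:
    """Continuous multichannel recording.

    data
        channels x samples array in microvolts, rows aligned with ``montage``.
    fs
        sampling rate in Hz.
    """

    data: np.ndarray
    fs: float
    montage: Montage = field(default_factory=Montage.default_30)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DataError("recording data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.montage):
            raise DataError(
                f"{self.data.shape[0]} data rows but montage has {len(self.montage)} channels"
            )
        if not self.fs > 0:
            raise ConfigError("sampling rate must be positive")
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            name = self.montage.labels[int(np.flatnonzero(bad)[0])]
            raise DataQualityError(f"non-finite samples in channel {name}")

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
    """Fixed-length labeled epochs: ``epochs`` is epoch x channel x sample."""

    epochs: np.ndarray
    labels: np.ndarray
    fs: float
    epoch_length_s: float = 1.0
    montage: Montage = field(default_factory=Montage.default_30)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise DataError("epochs must be 3-D (epoch x channel x sample)")
        if len(self.labels) != self.epochs.shape[0]:
            raise DataError("one label per epoch required")
        if not np.isin(self.labels, [LABEL_JX, LABEL_ZD]).all():
            raise DataError("labels must be 0 (JX) or 1 (ZD)")
        want = round(self.fs * self.epoch_length_s)
        if self.epochs.shape[2] != want:
            raise DataError(
                f"epoch sample dimension {self.epochs.shape[2]} != fs*epoch_length = {want}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def _read_delimited(path: Path) -> pd.DataFrame:
    head = path.open().readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    return pd.read_csv(path, sep=sep)


def load_recording(
    path: str | Path,
    format: str = "auto",
    montage: Montage | str = "auto",
    subject_id: str = "",
) -> Recording:
    """Load a recording from EDF or delimited text (channels as columns).

    Reference electrodes A1/A2 are dropped if present. With ``montage="auto"``
    the file's own channel order defines the montage; otherwise columns are
    re-ordered to the given montage and missing electrodes raise
    :class:`MontageMismatchError`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = list(raw.ch_names)
        data = raw.get_data() * 1e6  # mne returns volts
        fs = float(raw.info["sfreq"])
    elif format == "delimited":
        try:
            df = _read_delimited(path)
        except Exception as exc:  # noqa: BLE001 - surface as I/O error
            raise DataError(f"cannot parse {path}: {exc}") from exc
        names = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=np.float64).T
        fs = _infer_fs_from_sidecar(path)
    else:
        raise ConfigError(f"unknown format {format!r}")

    keep = [i for i, n in enumerate(names) if n not in REFERENCE_LABELS]
    names = [names[i] for i in keep]
    data = data[keep]

    if montage == "auto":
        mont = Montage(tuple(names))
    else:
        mont = montage
        missing = [lab for lab in mont.labels if lab not in names]
        if missing:
            raise MontageMismatchError(f"file lacks montage electrodes: {missing}")
        extra = [n for n in names if n not in mont.labels]
        if extra:
            raise MontageMismatchError(f"file has channels not in montage: {extra}")
        data = data[[names.index(lab) for lab in mont.labels]]

    return Recording(data=data, fs=fs, montage=mont, subject_id=subject_id)


def _infer_fs_from_sidecar(path: Path) -> float:
    """Delimited files carry no rate; look for ``<name>.fs`` sidecar, else 1000 Hz."""
    side = path.with_suffix(path.suffix + ".fs")
    if side.exists():
        return float(side.read_text().strip())
    return 1000.0


def save_recording_delimited(rec: Recording, path: str | Path) -> None:
    """Write channels-as-columns delimited text with an ``.fs`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.montage.labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    path.with_suffix(path.suffix + ".fs").write_text(f"{rec.fs:g}\n")


def resample(rec: Recording, target_fs: float) -> Recording:
    """Rate-reduce a recording with polyphase (zero-phase FIR) anti-aliasing."""
    if target_fs > rec.fs:
        raise UpsamplingError(f"cannot upsample {rec.fs} Hz -> {target_fs} Hz")
    if target_fs == rec.fs:
        return replace(rec, data=rec.data.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    data = resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, fs=float(target_fs))


def epoch(rec: Recording, label: int, epoch_length_s: float = 1.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs of one label.

    The trailing partial epoch is dropped; epoch count is
    ``floor(n_samples / (fs * epoch_length_s))``.
    """
    if label not in (LABEL_JX, LABEL_ZD):
        raise ConfigError("label must be 0 (JX) or 1 (ZD)")
    samples_per = round(rec.fs * epoch_length_s)
    n = rec.n_samples // samples_per
    if n < 1:
        raise EmptyEpochsError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{epoch_length_s}-s epoch at {rec.fs} Hz"
        )
    cut = rec.data[:, : n * samples_per]
    eps = cut.reshape(rec.n_channels, n, samples_per).transpose(1, 0, 2)
    return EpochSet(
        epochs=eps.copy(),
        labels=np.full(n, label, dtype=np.int64),
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        montage=rec.montage,
    )


def concat_epochs(parts: list[EpochSet]) -> EpochSet:
    """Stack epoch sets (same fs, epoch length and montage) along epochs."""
    if not parts:
        raise DataError("nothing to concatenate")
    first = parts[0]
    for p in parts[1:]:
        if p.fs != first.fs or p.epoch_length_s != first.epoch_length_s:
            raise DataError("epoch sets differ in fs or epoch length")
        if p.montage.labels != first.montage.labels:
            raise DataError("epoch sets differ in montage")
    return EpochSet(
        epochs=np.concatenate([p.epochs for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        fs=first.fs,
        epoch_length_s=first.epoch_length_s,
        montage=first.montage,
    )
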