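"""Electrode montages (10-20 system naming).

A montage is an ordered list of electrode names; channel *numbers* are the
1-based positions in that order, following the convention of 30-channel
fatigue-driving EEG caps (reference electrodes A1/A2 excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError

#: Default 30-channel montage: name -> 1-based number runs Fp1=1 ... O2=30.
DEFAULT_30_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT7", "FC3", "FCz",
    "FC4", "FT8", "T3", "C3", "Cz", "C4", "T4", "TP7", "CP3", "CPz",
    "CP4", "TP8", "T5", "P3", "Pz", "P4", "T6", "O1", "Oz", "O2",
)

#: Reference electrodes dropped on load when present.
REFERENCE_LABELS: tuple[str, ...] = ("A1", "A2")


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels; numbers are 1-based indices into ``labels``."""

    labels: tuple[str, ...] = field(default=DEFAULT_30_LABELS)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ConfigError("montage labels must be unique")
        if not self.labels:
            raise ConfigError("montage must have at least one electrode")
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def numbers(self) -> tuple[int, ...]:
        """1-based channel numbers aligned with :attr:`labels`."""
        return tuple(range(1, len(self.labels) + 1))

    def number_of(self, label: str) -> int:
        """1-based channel number of an electrode name."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise ConfigError(f"electrode {label!r} not in montage") from None

    def name_of(self, number: int) -> str:
        """Electrode name for a 1-based channel number."""
        if not 1 <= number <= len(self.labels):
            raise ConfigError(f"channel number {number} out of range 1..{len(self.labels)}")
        return self.labels[number - 1]

    @classmethod
    def default_30(cls) -> "Montage":
        return cls(DEFAULT_30_LABELS)

    @classmethod
    def from_file(cls, path: str | Path) -> "Montage":
        """Read a two-column text file: electrode name, 1-based number."""
        rows: list[tuple[int, str]] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ConfigError(f"bad montage line: {line!r}")
            name, num = parts
            rows.append((int(num), name))
        rows.sort()
        if [n for n, _ in rows] != list(range(1, len(rows) + 1)):
            raise ConfigError("montage numbers must be 1..N without gaps")
        return cls(tuple(name for _, name in rows))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{name}\t{i}\n" for i, name in zip(self.numbers, self.labels))
        )
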