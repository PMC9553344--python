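"""Synthetic two-state multichannel EEG generator.

Emulates the shape of a driving-fatigue study: per subject one resting (JX)
and one fatigued (ZD) continuous recording, 30 channels at 1000 Hz, 300 s per
state. Every channel carries 1/f-shaped background noise plus narrowband
alpha (10 Hz) and theta (6 Hz) oscillations. A configurable subset of
*informative* channels expresses the fatigue motif in the ZD state:

* theta amplitude multiplied by ``theta_power_shift`` (fatigue EEG shows
  elevated theta power), and
* background noise attenuated by ``1 - complexity_shift`` (the signal becomes
  more sinusoidal, i.e. more regular, so fuzzy entropy drops).

Non-informative channels are distributionally identical across states and
exchangeable with each other. Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import Recording, save_recording_delimited
from .errors import ConfigError
from .montage import Montage, DEFAULT_30_LABELS

#: Default informative set: occipital/temporal/parietal electrodes typically
#: implicated in fatigue studies — T6, O1, Oz, T4, P3, FC3 (1-based numbers).
DEFAULT_INFORMATIVE: tuple[int, ...] = (27, 28, 29, 17, 24, 9)


@dataclass(frozen=True)
class SynthSpec:
    """Generator conditions.

    Amplitudes are in microvolts and refer to the equivalent sine amplitude
    (component rms = amp / sqrt(2)): pink-noise background sd 10, alpha 8,
    theta 5 — typical scalp-EEG magnitudes. ``informative_channels`` are
    1-based channel numbers.
    """

    n_subjects: int = 10
    seconds_per_state: float = 300.0
    fs: float = 1000.0
    n_channels: int = 30
    informative_channels: tuple[int, ...] = DEFAULT_INFORMATIVE
    theta_power_shift: float = 2.0
    complexity_shift: float = 0.5
    noise_sd: float = 10.0
    alpha_amp: float = 8.0
    theta_amp: float = 5.0
    alpha_freq: float = 10.0
    theta_freq: float = 6.0
    osc_bandwidth: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ConfigError("counts must be positive")
        if self.seconds_per_state <= 0 or self.fs <= 0:
            raise ConfigError("durations and rates must be positive")
        if not self.theta_power_shift > 0:
            raise ConfigError("theta_power_shift must be > 0")
        if not 0 <= self.complexity_shift < 1:
            raise ConfigError("complexity_shift must be in [0, 1)")
        bad = [c for c in self.informative_channels if not 1 <= c <= self.n_channels]
        if bad:
            raise ConfigError(f"informative channels out of range: {bad}")

    def montage(self) -> Montage:
        if self.n_channels == len(DEFAULT_30_LABELS):
            return Montage(DEFAULT_30_LABELS)
        return Montage(tuple(f"CH{i}" for i in range(1, self.n_channels + 1)))


def _shaped_noise(
    rng: np.random.Generator, n: int, fs: float, shaping: np.ndarray
) -> np.ndarray:
    """Gaussian noise with the given rfft amplitude shaping, unit sd."""
    spec = np.fft.rfft(rng.standard_normal(n))
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_shaping(n: int, fs: float) -> np.ndarray:
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    return 1.0 / np.sqrt(np.maximum(f, 1.0))


def _band_shaping(n: int, fs: float, f0: float, bw: float) -> np.ndarray:
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = bw / 2.0
    return np.exp(-0.5 * ((f - f0) / sigma) ** 2)


def _channel_signal(
    rng: np.random.Generator, spec: SynthSpec, informative: bool, fatigued: bool
) -> np.ndarray:
    """One channel of one state recording.

    Oscillations are narrowband Gaussian processes (random phase diffusing
    on the ~1/bandwidth timescale), not fixed-phase sinusoids: a fixed phase
    per recording would give every recording a persistent spectral-leakage
    fingerprint that a classifier could exploit as recording identity even
    with no planted state effect. Each component is normalised to its target
    power per recording, so only the planted shifts distinguish states.
    """
    n = round(spec.seconds_per_state * spec.fs)
    theta_amp = spec.theta_amp
    noise_sd = spec.noise_sd
    if informative and fatigued:
        theta_amp *= spec.theta_power_shift
        noise_sd *= 1.0 - spec.complexity_shift
    root2 = np.sqrt(2.0)
    noise = noise_sd * _shaped_noise(rng, n, spec.fs, _pink_shaping(n, spec.fs))
    alpha = (spec.alpha_amp / root2) * _shaped_noise(
        rng, n, spec.fs, _band_shaping(n, spec.fs, spec.alpha_freq, spec.osc_bandwidth)
    )
    theta = (theta_amp / root2) * _shaped_noise(
        rng, n, spec.fs, _band_shaping(n, spec.fs, spec.theta_freq, spec.osc_bandwidth)
    )
    return noise + alpha + theta


def generate(spec: SynthSpec) -> tuple[list[tuple[Recording, Recording]], list[int]]:
    """Per subject a (JX, ZD) recording pair, plus the informative channels.

    Returns
    -------
    pairs : list of (resting, fatigued) :class:`Recording` per subject.
    ground_truth : 1-based informative channel numbers, as configured.
    """
    rng = np.random.default_rng(spec.seed)
    montage = spec.montage()
    informative = set(spec.informative_channels)
    pairs = []
    for s in range(spec.n_subjects):
        recs = []
        for fatigued in (False, True):
            data = np.empty((spec.n_channels, round(spec.seconds_per_state * spec.fs)))
            for c in range(spec.n_channels):
                data[c] = _channel_signal(rng, spec, (c + 1) in informative, fatigued)
            recs.append(
                Recording(
                    data=data,
                    fs=spec.fs,
                    montage=montage,
                    subject_id=f"S{s + 1:02d}",
                )
            )
        pairs.append((recs[0], recs[1]))
    return pairs, list(spec.informative_channels)


def write_dataset(
    pairs: list[tuple[Recording, Recording]],
    ground_truth: list[int],
    spec: SynthSpec,
    out_dir: str | Path,
) -> Path:
    """Write delimited recordings plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for jx, zd in pairs:
        sid = jx.subject_id
        jx_path = out / f"{sid}_JX.tsv"
        zd_path = out / f"{sid}_ZD.tsv"
        save_recording_delimited(jx, jx_path)
        save_recording_delimited(zd, zd_path)
        entries.append({"subject": sid, "jx": jx_path.name, "zd": zd_path.name})
    manifest = {
        "spec": asdict(spec),
        "ground_truth_channels": list(ground_truth),
        "recordings": entries,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath
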