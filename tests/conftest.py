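from __future__ import annotations

import numpy as np
import pytest

from eegchansel import (
    EpochSet,
    EvalParams,
    Montage,
    ReliefFParams,
    SynthSpec,
    concat_epochs,
    epoch,
    fe_features,
    fuse,
    generate,
    relieff_sfs,
    resample,
    subband_std_features,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_epochs(n_epochs=8, n_channels=3, fs=128.0, seed=0, labels=None) -> EpochSet:
    """Random labeled epochs for unit tests."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_epochs, n_channels, int(fs)))
    if labels is None:
        labels = np.arange(n_epochs) % 2
    mont = Montage(tuple(f"CH{i+1}" for i in range(n_channels)))
    return EpochSet(epochs=eps, labels=np.asarray(labels), fs=fs, montage=mont)


def planted_epoch_set(seed: int, n_subjects=2, seconds=60.0, **spec_kw) -> tuple:
    """Reduced-scale planted-signal dataset run through resample+epoch.

    Returns (EpochSet at 128 Hz, 1-based informative channel numbers).
    """
    spec = SynthSpec(
        n_subjects=n_subjects, seconds_per_state=seconds, seed=seed, **spec_kw
    )
    pairs, truth = generate(spec)
    parts = []
    for jx, zd in pairs:
        parts.append(epoch(resample(jx, 128.0), 0))
        parts.append(epoch(resample(zd, 128.0), 1))
    return concat_epochs(parts), truth


class PlantedRun:
    """Selection results on one seeded planted dataset, all three feature sets."""

    def __init__(self, seed: int):
        epochs, truth = planted_epoch_set(seed)
        theta = subband_std_features(epochs)["Theta"]
        fe = fe_features(epochs)
        fused = fuse(theta, fe)
        p = ReliefFParams(seed=seed)
        ep = EvalParams(seed=seed)
        self.truth = set(truth)
        self.theta = relieff_sfs(theta, p, ep)
        self.fe = relieff_sfs(fe, p, ep)
        self.fused = relieff_sfs(fused, p, ep)


@pytest.fixture(scope="session")
def planted_runs() -> list[PlantedRun]:
    """Twenty seeded end-to-end runs at reduced scale (2 subjects, 60 s/state)."""
    return [PlantedRun(seed) for seed in range(20)]
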