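"""Per-epoch, per-channel features and feature-matrix construction.

Two feature families are extracted from each 1-second epoch of each channel:

* **Subband standard deviation** — a 6-level wavelet packet decomposition
  (WPD) splits the 0..fs/2 range into equal-width leaves (1 Hz at 128 Hz);
  the classical EEG bands Theta (4-8 Hz), Alpha (8-13 Hz), Beta1 (13-20 Hz)
  and Beta2 (20-30 Hz) are reconstructed from the leaves whose natural
  frequency intervals fall inside each band, and the population standard
  deviation of each band-limited signal is the feature.
* **Fuzzy entropy (FE)** — a regularity statistic comparing the similarity
  of embedded windows of length m against length m+1 under an exponential
  fuzzy membership; irregular signals score high, near-periodic ones low.

Feature matrices are epochs x (channels * features_per_channel), channel-major,
so that fusing two single-feature matrices interleaves each channel's columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt

from .core import EpochSet
from .errors import ConfigError, DataError, FusionError

#: EEG band edges in Hz, half-open intervals [lo, hi).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "Beta1": (13.0, 20.0),
    "Beta2": (20.0, 30.0),
}


@dataclass(frozen=True)
class WPDConfig:
    """Wavelet packet decomposition settings.

    ``levels=6`` at fs=128 Hz gives 64 leaves of 1 Hz bandwidth, so every
    default band edge falls on a leaf boundary. ``db16`` with periodized
    extension keeps the transform orthonormal on 1-s epochs (exact leaf
    energy conservation) with steep enough filters for clean band splits.
    """

    levels: int = 6
    wavelet: str = "db16"
    mode: str = "periodization"
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        ivs = sorted(self.bands.values())
        for (lo, hi) in ivs:
            if not lo < hi:
                raise ConfigError(f"empty band [{lo}, {hi})")
        for (_, h1), (l2, _) in zip(ivs, ivs[1:]):
            if l2 < h1:
                raise ConfigError("bands must be disjoint")

    def leaf_bandwidth(self, fs: float) -> float:
        return (fs / 2.0) / 2**self.levels

    def band_leaf_indices(self, fs: float) -> dict[str, range]:
        """Frequency-ordered leaf index range for each band.

        Leaf i covers [i*bw, (i+1)*bw); band edges must sit on leaf
        boundaries and below the Nyquist rate.
        """
        bw = self.leaf_bandwidth(fs)
        out: dict[str, range] = {}
        for name, (lo, hi) in self.bands.items():
            if hi > fs / 2.0:
                raise ConfigError(f"band {name} [{lo},{hi}) exceeds Nyquist {fs/2}")
            ilo, ihi = lo / bw, hi / bw
            if abs(ilo - round(ilo)) > 1e-9 or abs(ihi - round(ihi)) > 1e-9:
                raise ConfigError(
                    f"band {name} edge not a multiple of leaf bandwidth {bw} Hz"
                )
            out[name] = range(round(ilo), round(ihi))
        return out


@dataclass(frozen=True)
class FuzzyEntropyParams:
    """Fuzzy entropy settings: window m, tolerance r, membership exponent.

    With ``r_mode="relative"`` the tolerance is r times the signal's standard
    deviation, making FE invariant to amplitude scaling; ``"absolute"`` uses
    r in signal units directly.
    """

    m: int = 2
    r: float = 0.25
    n_exp: float = 2.0
    r_mode: str = "relative"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if not self.r > 0:
            raise ConfigError("r must be > 0")
        if not self.n_exp > 0:
            raise ConfigError("n_exp must be > 0")
        if self.r_mode not in ("relative", "absolute"):
            raise ConfigError("r_mode must be 'relative' or 'absolute'")


@dataclass
class FeatureMatrix:
    """Epochs x columns feature values with labels and a column->channel map."""

    values: np.ndarray
    labels: np.ndarray
    column_map: list[tuple[int, str]]  # (0-based channel index, feature name)
    channel_names: list[str]
    features_per_channel: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise DataError("feature values must be 2-D")
        if self.values.shape[0] != len(self.labels):
            raise DataError("one label per epoch row required")
        if self.values.shape[1] != len(self.column_map):
            raise DataError("column_map must describe every column")
        n_ch = len(self.channel_names)
        if self.values.shape[1] != n_ch * self.features_per_channel:
            raise DataError("columns != channels * features_per_channel")
        # channel-major grouping: columns of channel c occupy a contiguous block
        expect = [c for c in range(n_ch) for _ in range(self.features_per_channel)]
        if [c for c, _ in self.column_map] != expect:
            raise DataError("column_map must be channel-major")
        if not np.isfinite(self.values).all():
            raise DataError("non-finite feature values")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel_columns(self, channel: int) -> list[int]:
        """Column indices belonging to a 0-based channel index."""
        f = self.features_per_channel
        return list(range(channel * f, (channel + 1) * f))


def epoch_std(signal: np.ndarray) -> float:
    """Population standard deviation (divisor N) of a sequence."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise DataError("empty sequence has no standard deviation")
    return float(np.std(signal))


# ---------------------------------------------------------------------------
# Wavelet packet machinery: batched along the first axis for throughput.
# Leaf coefficients and selective reconstructions match pywt.WaveletPacket
# exactly (checked in the test suite); frequency ordering of the leaves is
# taken from pywt's sequency ordering, not the raw tree order.
# ---------------------------------------------------------------------------

def _freq_ordered_paths(cfg: WPDConfig) -> list[str]:
    wp = pywt.WaveletPacket(
        np.zeros(2**cfg.levels), cfg.wavelet, mode=cfg.mode, maxlevel=cfg.levels
    )
    return [node.path for node in wp.get_level(cfg.levels, order="freq")]


def _wpd_decompose(data: np.ndarray, cfg: WPDConfig) -> dict[str, np.ndarray]:
    """Full packet tree of a (batch, samples) array; keys are a/d paths."""
    nodes: dict[str, np.ndarray] = {"": data}
    frontier = [""]
    for _ in range(cfg.levels):
        nxt = []
        for p in frontier:
            a, d = pywt.dwt(nodes[p], cfg.wavelet, mode=cfg.mode, axis=-1)
            nodes[p + "a"], nodes[p + "d"] = a, d
            nxt += [p + "a", p + "d"]
        frontier = nxt
    return nodes

def _wpd_reconstruct(
    nodes: dict[str, np.ndarray], keep: set[str], cfg: WPDConfig, n_samples: int
) -> np.ndarray:
    """Inverse packet transform retaining only the ``keep`` leaves."""
    cur = {
        p: (v if p in keep else np.zeros_like(v))
        for p, v in nodes.items()
        if len(p) == cfg.levels
    }
    for _ in range(cfg.levels):
        parents = {q[:-1] for q in cur}
        nxt = {}
        for p in parents:
            r = pywt.idwt(cur[p + "a"], cur[p + "d"], cfg.wavelet, mode=cfg.mode, axis=-1)
            nxt[p] = r[..., : nodes[p].shape[-1]]
        cur = nxt
    return cur[""][..., :n_samples]


def _wpd_bands_batch(
    data: np.ndarray, fs: float, cfg: WPDConfig
) -> dict[str, np.ndarray]:
    """Band-limited reconstructions of a (batch, samples) array."""
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[-1]
    min_len = 2**cfg.levels
    if n < min_len:
        raise DataError(
            f"epoch of {n} samples too short for a {cfg.levels}-level decomposition"
        )
    band_leaves = cfg.band_leaf_indices(fs)
    paths = _freq_ordered_paths(cfg)
    nodes = _wpd_decompose(data, cfg)
    return {
        name: _wpd_reconstruct(nodes, {paths[i] for i in leaves}, cfg, n)
        for name, leaves in band_leaves.items()
    }


def wpd_subband_signals(
    epoch: np.ndarray, fs: float, cfg: WPDConfig | None = None
) -> dict[str, np.ndarray]:
    """Band-limited reconstructions of one epoch, one signal per EEG band."""
    cfg = cfg or WPDConfig()
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 1:
        raise DataError("epoch must be 1-D")
    return {k: v[0] for k, v in _wpd_bands_batch(epoch[None, :], fs, cfg).items()}


def wpd_leaf_coefficients(
    epoch: np.ndarray, fs: float, cfg: WPDConfig | None = None
) -> list[np.ndarray]:
    """Terminal-node coefficient arrays in natural frequency order."""
    cfg = cfg or WPDConfig()
    nodes = _wpd_decompose(np.asarray(epoch, dtype=np.float64)[None, :], cfg)
    return [nodes[p][0] for p in _freq_ordered_paths(cfg)]


def subband_std_features(
    epochs: EpochSet, cfg: WPDConfig | None = None
) -> dict[str, FeatureMatrix]:
    """One epochs x channels Std feature matrix per EEG band."""
    cfg = cfg or WPDConfig()
    E, C, S = epochs.epochs.shape
    flat = epochs.epochs.reshape(E * C, S)
    bands = _wpd_bands_batch(flat, epochs.fs, cfg)
    names = list(epochs.montage.labels)
    out = {}
    for band, sig in bands.items():
        vals = sig.std(axis=-1).reshape(E, C)
        out[band] = FeatureMatrix(
            values=vals,
            labels=epochs.labels.copy(),
            column_map=[(c, f"{band}_Std") for c in range(C)],
            channel_names=names,
        )
    return out


# ---------------------------------------------------------------------------
# Fuzzy entropy
# ---------------------------------------------------------------------------

def _fe_batch(X: np.ndarray, p: FuzzyEntropyParams) -> np.ndarray:
    """Fuzzy entropy of each row of a (batch, n) array.

    Both window sizes m and m+1 use the same K = n - m starting indices, so
    the m+1 Chebyshev distance dominates the m distance pairwise and
    Phi^{m+1} <= Phi^m (FE >= 0) holds by construction.
    """
    X = np.asarray(X, dtype=np.float64)
    B, N = X.shape
    K = N - p.m
    if K < 2:
        raise DataError(f"sequence of {N} samples too short for m={p.m} (need >= m+2)")
    sd = X.std(axis=1)
    if p.r_mode == "relative":
        r_eff = p.r * sd
    else:
        r_eff = np.full(B, p.r)
    live = (sd > 0) & (r_eff > 0)
    out = np.zeros(B)
    if not live.any():
        return out
    Xl = X[live]
    rl = r_eff[live]
    nb = Xl.shape[0]
    idx = np.arange(K)

    # Chebyshev distances over windows of length m, then extended to m+1.
    D = np.zeros((nb, K, K))
    for t in range(p.m):
        seg = Xl[:, t : t + K]
        np.maximum(D, np.abs(seg[:, :, None] - seg[:, None, :]), out=D)

    def phi(dist: np.ndarray) -> np.ndarray:
        z = dist / rl[:, None, None]
        z = z * z if p.n_exp == 2.0 else z**p.n_exp
        mem = np.exp(-z)
        mem[:, idx, idx] = 0.0  # exclude self-matches
        return mem.sum(axis=2).mean(axis=1) / (K - 1)

    phi_m = phi(D)
    seg = Xl[:, p.m : p.m + K]
    np.maximum(D, np.abs(seg[:, :, None] - seg[:, None, :]), out=D)
    phi_m1 = phi(D)
    with np.errstate(divide="ignore"):
        out[live] = np.log(phi_m) - np.log(phi_m1)
    return out


def fuzzy_entropy(signal: np.ndarray, p: FuzzyEntropyParams | None = None) -> float:
    """Fuzzy entropy ln Phi^m - ln Phi^{m+1} of a sequence.

    A constant sequence has zero entropy by definition (all distances are
    zero, every membership is one).
    """
    p = p or FuzzyEntropyParams()
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise DataError("signal must be 1-D")
    return float(_fe_batch(signal[None, :], p)[0])


def fe_features(
    epochs: EpochSet, p: FuzzyEntropyParams | None = None, chunk: int = 512
) -> FeatureMatrix:
    """Epochs x channels fuzzy entropy feature matrix."""
    p = p or FuzzyEntropyParams()
    E, C, S = epochs.epochs.shape
    flat = epochs.epochs.reshape(E * C, S)
    vals = np.concatenate(
        [_fe_batch(flat[i : i + chunk], p) for i in range(0, flat.shape[0], chunk)]
    ).reshape(E, C)
    return FeatureMatrix(
        values=vals,
        labels=epochs.labels.copy(),
        column_map=[(c, "FE") for c in range(C)],
        channel_names=list(epochs.montage.labels),
    )


def fuse(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Channel-major interleave of two single-feature matrices (a first)."""
    if a.features_per_channel != 1 or b.features_per_channel != 1:
        raise FusionError("fusion takes two single-feature matrices")
    if a.values.shape[0] != b.values.shape[0]:
        raise FusionError("epoch counts differ")
    if not np.array_equal(a.labels, b.labels):
        raise FusionError("labels differ")
    if a.channel_names != b.channel_names:
        raise FusionError("channel sets/order differ")
    C = a.n_channels
    vals = np.empty((a.n_epochs, 2 * C))
    vals[:, 0::2] = a.values
    vals[:, 1::2] = b.values
    cmap = []
    for c in range(C):
        cmap.append((c, a.column_map[c][1]))
        cmap.append((c, b.column_map[c][1]))
    return FeatureMatrix(
        values=vals,
        labels=a.labels.copy(),
        column_map=cmap,
        channel_names=list(a.channel_names),
        features_per_channel=2,
    )


def unfuse(fm: FeatureMatrix) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Inverse of :func:`fuse` using the column map."""
    if fm.features_per_channel != 2:
        raise FusionError("only 2-feature matrices can be un-fused")
    def pick(offset: int) -> FeatureMatrix:
        cols = list(range(offset, fm.values.shape[1], 2))
        return FeatureMatrix(
            values=fm.values[:, cols].copy(),
            labels=fm.labels.copy(),
            column_map=[fm.column_map[i] for i in cols],
            channel_names=list(fm.channel_names),
        )
    return pick(0), pick(1)


# ---------------------------------------------------------------------------
# Serialization: delimited text, two header rows (channel, feature) + label
# ---------------------------------------------------------------------------

def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        chans = "\t".join(fm.channel_names[c] for c, _ in fm.column_map)
        feats = "\t".join(name for _, name in fm.column_map)
        fh.write(f"label\t{chans}\n")
        fh.write(f"\t{feats}\n")
        for row, lab in zip(fm.values, fm.labels):
            cells = "\t".join(f"{v:.17g}" for v in row)
            fh.write(f"{lab}\t{cells}\n")


def read_feature_matrix(fm_path: str | Path) -> FeatureMatrix:
    lines = Path(fm_path).read_text().splitlines()
    if len(lines) < 3:
        raise DataError("feature matrix file too short")
    chan_row = lines[0].split("\t")[1:]
    feat_row = lines[1].split("\t")[1:]
    channel_names = list(dict.fromkeys(chan_row))
    index = {n: i for i, n in enumerate(channel_names)}
    column_map = [(index[c], f) for c, f in zip(chan_row, feat_row)]
    labels, rows = [], []
    for line in lines[2:]:
        parts = line.split("\t")
        labels.append(int(parts[0]))
        rows.append([float(x) for x in parts[1:]])
    fpc = len(chan_row) // len(channel_names)
    return FeatureMatrix(
        values=np.array(rows),
        labels=np.array(labels),
        column_map=column_map,
        channel_names=channel_names,
        features_per_channel=fpc,
    )
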