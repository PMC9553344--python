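"""End-to-end orchestration: load -> resample -> epoch -> features -> select.

The pipeline reproduces the standard procedure: downsample each recording to
128 Hz, cut non-overlapping 1-second epochs labeled JX (rest, 0) or ZD
(fatigue, 1), extract the configured feature per channel per epoch, optionally
fuse two features channel-wise, then run the weight-ordered subset search and
report the optimal channel subset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    LABEL_JX,
    LABEL_ZD,
    EpochSet,
    concat_epochs,
    epoch,
    load_recording,
    resample,
)
from .errors import ConfigError, DataError
from .features import (
    FeatureMatrix,
    FuzzyEntropyParams,
    WPDConfig,
    fe_features,
    fuse,
    subband_std_features,
    write_feature_matrix,
)
from .montage import Montage
from .selection import EvalParams, ReliefFParams, SelectionResult, relieff_sfs

log = logging.getLogger("eegchansel")

SINGLE_FEATURES = ("Theta_Std", "Alpha_Std", "Beta1_Std", "Beta2_Std", "FE")


def known_feature_sets() -> list[str]:
    return list(SINGLE_FEATURES) + [f"{b}_Std+FE" for b in ("Theta", "Alpha", "Beta1", "Beta2")]


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults reproduce the standard procedure."""

    inputs: list[dict] = field(default_factory=list)  # {"jx": path, "zd": path}
    input_format: str = "auto"
    feature: str = "Theta_Std+FE"
    analysis_fs: float = 128.0
    epoch_length_s: float = 1.0
    wpd: WPDConfig = field(default_factory=WPDConfig)
    fe: FuzzyEntropyParams = field(default_factory=FuzzyEntropyParams)
    relieff: ReliefFParams = field(default_factory=ReliefFParams)
    eval: EvalParams = field(default_factory=EvalParams)
    weight_scale: float = 1e-3  # ranking tables print weight / weight_scale
    out_dir: str = "eegchansel_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        try:
            if "wpd" in kwargs and not isinstance(kwargs["wpd"], WPDConfig):
                wpd_kwargs = dict(kwargs["wpd"])
                if "bands" in wpd_kwargs:
                    wpd_kwargs["bands"] = {
                        k: tuple(v) for k, v in wpd_kwargs["bands"].items()
                    }
                kwargs["wpd"] = WPDConfig(**wpd_kwargs)
            if "fe" in kwargs and not isinstance(kwargs["fe"], FuzzyEntropyParams):
                kwargs["fe"] = FuzzyEntropyParams(**kwargs["fe"])
            if "relieff" in kwargs and not isinstance(kwargs["relieff"], ReliefFParams):
                kwargs["relieff"] = ReliefFParams(**kwargs["relieff"])
            if "eval" in kwargs and not isinstance(kwargs["eval"], EvalParams):
                kwargs["eval"] = EvalParams(**kwargs["eval"])
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["wpd"]["bands"] = {k: list(v) for k, v in d["wpd"]["bands"].items()}
        return d

    def content_hash(self) -> str:
        """Hash of everything that determines the result (output path excluded)."""
        d = self.to_jsonable()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_epochs(cfg: PipelineConfig, montage: Montage | str = "auto") -> EpochSet:
    if not cfg.inputs:
        raise ConfigError("no input recordings configured")
    parts = []
    for entry in cfg.inputs:
        for key, label in (("jx", LABEL_JX), ("zd", LABEL_ZD)):
            if key not in entry:
                raise ConfigError(f"input entry missing {key!r} path: {entry}")
            rec = load_recording(entry[key], format=cfg.input_format, montage=montage)
            rec = resample(rec, cfg.analysis_fs)
            es = epoch(rec, label, cfg.epoch_length_s)
            log.info(
                "loaded %s: %d epochs x %d channels x %d samples (label %d)",
                entry[key], es.n_epochs, es.n_channels, es.epochs.shape[2], label,
            )
            parts.append(es)
    return concat_epochs(parts)


def extract_feature_matrix(epochs: EpochSet, cfg: PipelineConfig) -> FeatureMatrix:
    """Build the configured single or fused feature matrix from epochs."""
    name = cfg.feature
    if name not in known_feature_sets():
        raise ConfigError(f"unknown feature set {name!r}; known: {known_feature_sets()}")
    if name.endswith("+FE"):
        band = name[: -len("_Std+FE")]
        std = subband_std_features(epochs, cfg.wpd)[band]
        fe = fe_features(epochs, cfg.fe)
        return fuse(std, fe)
    if name == "FE":
        return fe_features(epochs, cfg.fe)
    band = name[: -len("_Std")]
    return subband_std_features(epochs, cfg.wpd)[band]


def _write_outputs(
    cfg: PipelineConfig, fm: FeatureMatrix, result: SelectionResult, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": cfg.content_hash(),
        "seeds": {"relieff": cfg.relieff.seed, "eval": cfg.eval.seed},
    }
    r = result.ranking
    rank_df = pd.DataFrame(
        {
            "channel_number": [int(i) + 1 for i in r.order],
            "channel_name": [r.channel_names[i] for i in r.order],
            f"weight_x{cfg.weight_scale:g}": [
                f"{r.weights[i] / cfg.weight_scale:.4f}" for i in r.order
            ],
        }
    )
    rank_df.to_csv(out / "ranking.tsv", sep="\t", index=False)
    acc_df = pd.DataFrame(
        {
            "n_channels": np.arange(1, len(result.accuracy_by_size) + 1),
            "accuracy_pct": [f"{a * 100:.2f}" for a in result.accuracy_by_size],
        }
    )
    acc_df.to_csv(out / "accuracy_by_size.tsv", sep="\t", index=False)
    payload = {
        "provenance": provenance,
        "feature": cfg.feature,
        "n_epochs": int(fm.n_epochs),
        "n_channels": int(fm.n_channels),
        "optimal_size": int(result.optimal_size),
        "optimal_channels": result.optimal_channels,
        "optimal_channel_numbers": [int(i) + 1 for i in result.ranking.order[: result.optimal_size]],
        "optimal_accuracy": round(result.optimal_accuracy, 6),
        "accuracy_by_size": [round(float(a), 6) for a in result.accuracy_by_size],
        "weights": [round(float(w), 10) for w in r.weights],
    }
    (out / "result.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    write_feature_matrix(fm, out / "features.tsv")
    summary = (
        f"feature set: {cfg.feature}\n"
        f"optimal subset size: {result.optimal_size} of {fm.n_channels}\n"
        f"optimal channels: {', '.join(result.optimal_channels)}\n"
        f"optimal accuracy: {result.optimal_accuracy * 100:.2f}%\n"
    )
    (out / "summary.txt").write_text(summary)


def run_pipeline(cfg: PipelineConfig, montage: Montage | str = "auto") -> SelectionResult:
    """Execute the full selection pipeline and write report files."""
    epochs = _load_epochs(cfg, montage)
    log.info("total: %d epochs (%d JX / %d ZD)", epochs.n_epochs,
             int((epochs.labels == 0).sum()), int((epochs.labels == 1).sum()))
    fm = extract_feature_matrix(epochs, cfg)
    log.info("feature matrix: %d x %d (%s)", fm.n_epochs, fm.values.shape[1], cfg.feature)
    result = relieff_sfs(fm, cfg.relieff, cfg.eval)
    if result.optimal_size == fm.n_channels:
        log.warning("maximum accuracy only attained with the full channel set")
    _write_outputs(cfg, fm, result, Path(cfg.out_dir))
    return result


def compare_features(
    cfg: PipelineConfig, feature_sets: list[str], montage: Montage | str = "auto"
) -> pd.DataFrame:
    """One row per feature set: optimal subset size and accuracy."""
    if not feature_sets:
        raise ConfigError("feature set list must be non-empty")
    for name in feature_sets:
        if name not in known_feature_sets():
            raise ConfigError(f"unknown feature set {name!r}")
    epochs = _load_epochs(cfg, montage)
    rows = []
    for name in feature_sets:
        sub = PipelineConfig(**{**cfg.__dict__, "feature": name})
        fm = extract_feature_matrix(epochs, sub)
        result = relieff_sfs(fm, cfg.relieff, cfg.eval)
        rows.append(
            {
                "feature": name,
                "n_channels": result.optimal_size,
                "accuracy_pct": round(result.optimal_accuracy * 100, 2),
                "channels": ", ".join(result.optimal_channels),
            }
        )
    df = pd.DataFrame(rows)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "comparison.tsv", sep="\t", index=False)
    return df


def plot_accuracy_curve(result: SelectionResult, path: str | Path) -> None:
    """Accuracy vs subset size figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = np.arange(1, len(result.accuracy_by_size) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sizes, result.accuracy_by_size * 100, marker="o", ms=3)
    ax.axvline(result.optimal_size, color="crimson", ls="--", lw=1,
               label=f"optimal size = {result.optimal_size}")
    ax.set_xlabel("number of channels")
    ax.set_ylabel("accuracy (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
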