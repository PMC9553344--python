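"""Channel weighting and subset selection (the ReliefF-SFS method).

The core idea: weight every channel with the two-class ReliefF statistic,
then grow channel subsets in descending-weight order (a degenerate but fast
form of sequential forward selection) and score each subset with K-nearest-
neighbour accuracy under stratified 5-fold cross-validation. The optimal
subset is the smallest one attaining the maximum accuracy. A classical
accuracy-greedy SFS is provided as an alternate search mode.

Estimators follow scikit-learn conventions (``fit`` / ``transform`` /
``get_support``) and compose with sklearn pipelines; the module-level
functions are thin wrappers operating on :class:`~eegchansel.features.FeatureMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import ConfigError, DataError
from .features import FeatureMatrix


@dataclass(frozen=True)
class ReliefFParams:
    """ReliefF sampling parameters: m_iter sampled instances, k_nn neighbours."""

    m_iter: int = 80
    k_nn: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_iter < 1 or self.k_nn < 1:
            raise ConfigError("m_iter and k_nn must be >= 1")


@dataclass(frozen=True)
class EvalParams:
    """Subset evaluation parameters: KNN neighbour count and CV folds."""

    K: int = 10
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")


@dataclass
class ChannelRanking:
    """Per-channel ReliefF weights sorted descending."""

    weights: np.ndarray          # per channel, input order
    order: np.ndarray            # channel indices, best first
    feature_weights: np.ndarray  # per column, before per-channel averaging
    channel_names: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts; positive class is ZD (label 1)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def accuracy(self) -> float:
        """Acc = (TP + TN) / (TP + TN + FP + FN)."""
        if self.n == 0:
            raise DataError("no test samples")
        return (self.TP + self.TN) / self.n


@dataclass
class SelectionResult:
    """Accuracy for every subset size plus the optimal (smallest best) subset."""

    ranking: ChannelRanking
    accuracy_by_size: np.ndarray
    optimal_size: int
    optimal_channels: list[str]

    @property
    def optimal_accuracy(self) -> float:
        return float(self.accuracy_by_size[self.optimal_size - 1])


def _minmax_scale(X: np.ndarray) -> np.ndarray:
    """Min-max scale columns to [0,1]; constant columns map to zeros."""
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    safe = np.where(rng > 0, rng, 1.0)
    out = (X - lo) / safe
    out[:, rng == 0] = 0.0
    return out


def _relieff_feature_weights(
    X: np.ndarray, y: np.ndarray, m_iter: int, k_nn: int, seed: int
) -> np.ndarray:
    """Two-class ReliefF column weights.

    Instances are sampled uniformly without replacement; for each, the k_nn
    nearest same-class (hits) and other-class (misses) neighbours, by
    Euclidean distance on min-max scaled columns, push each column's weight
    down by the mean |diff| to hits and up by the mean |diff| to misses.
    Scaling to [0,1] doubles as the per-column value-range normalisation, and
    zeroes the contribution of constant columns.
    """
    n, _ = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise DataError("ReliefF here is two-class; need exactly 2 labels")
    if counts.min() < k_nn + 1:
        raise ConfigError(
            f"each class needs > k_nn={k_nn} samples (got {counts.min()})"
        )
    Xs = _minmax_scale(np.asarray(X, dtype=np.float64))
    rng = np.random.default_rng(seed)
    m_eff = min(m_iter, n)
    sampled = rng.choice(n, size=m_eff, replace=False)
    W = np.zeros(X.shape[1])
    for i in sampled:
        diff = np.abs(Xs - Xs[i])          # (n, cols)
        dist = np.sqrt((diff**2).sum(axis=1))
        same = y == y[i]
        hit_pool = np.flatnonzero(same)
        hit_pool = hit_pool[hit_pool != i]
        miss_pool = np.flatnonzero(~same)
        hits = hit_pool[np.argsort(dist[hit_pool], kind="stable")[:k_nn]]
        misses = miss_pool[np.argsort(dist[miss_pool], kind="stable")[:k_nn]]
        W += diff[misses].mean(axis=0) - diff[hits].mean(axis=0)
    return W / m_eff


class ReliefFWeighting(BaseEstimator):
    """ReliefF column weighting aggregated to per-channel weights.

    Parameters
    ----------
    m_iter, k_nn : ReliefF sampling instance and neighbour counts.
    features_per_channel : adjacent-column group size; channel weight is the
        mean of its columns' weights.
    random_state : seed for instance sampling.

    Attributes
    ----------
    feature_weights_ : per-column ReliefF weights.
    weights_ : per-channel weights (column weights averaged per channel).
    order_ : channel indices sorted by weight descending (ties: lower index).
    """

    def __init__(
        self,
        m_iter: int = 80,
        k_nn: int = 10,
        features_per_channel: int = 1,
        random_state: int = 0,
    ):
        self.m_iter = m_iter
        self.k_nn = k_nn
        self.features_per_channel = features_per_channel
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        ReliefFParams(m_iter=self.m_iter, k_nn=self.k_nn)  # validate
        f = self.features_per_channel
        if X.shape[1] % f:
            raise ConfigError("columns not divisible by features_per_channel")
        self.feature_weights_ = _relieff_feature_weights(
            X, y, self.m_iter, self.k_nn, self.random_state
        )
        self.weights_ = self.feature_weights_.reshape(-1, f).mean(axis=1)
        # stable sort on negated weights -> ties broken by lower channel index
        self.order_ = np.argsort(-self.weights_, kind="stable")
        return self

    def ranking(self, channel_names: list[str] | None = None) -> ChannelRanking:
        check_is_fitted(self)
        names = channel_names or [str(i + 1) for i in range(len(self.weights_))]
        return ChannelRanking(
            weights=self.weights_.copy(),
            order=self.order_.copy(),
            feature_weights=self.feature_weights_.copy(),
            channel_names=list(names),
        )


def _pooled_knn_cv(
    X: np.ndarray, y: np.ndarray, K: int, folds: int, seed: int
) -> ConfusionCounts:
    """Stratified shuffled k-fold KNN, confusion counts pooled over folds.

    Columns are min-max scaled with training-fold ranges before the distance
    computation: a Euclidean metric over mixed feature families (microvolt
    subband Std next to dimensionless FE) is otherwise dominated by whichever
    family has the larger numeric range.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for tr, te in skf.split(X, y):
        if K >= len(tr):
            raise ConfigError(f"K={K} >= training fold size {len(tr)}")
        lo = X[tr].min(axis=0)
        rng = X[tr].max(axis=0) - lo
        rng = np.where(rng > 0, rng, 1.0)
        Xtr = (X[tr] - lo) / rng
        Xte = (X[te] - lo) / rng
        clf = KNeighborsClassifier(n_neighbors=K, metric="euclidean")
        clf.fit(Xtr, y[tr])
        pred = clf.predict(Xte)
        truth = y[te]
        tp += int(((pred == 1) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _subset_columns(subset, features_per_channel: int) -> list[int]:
    f = features_per_channel
    return [c * f + j for c in subset for j in range(f)]


def _optimal_size(acc: np.ndarray) -> int:
    """Smallest subset size attaining the maximum accuracy."""
    return int(np.argmax(acc)) + 1  # argmax returns the first maximum


class _BaseSFS(SelectorMixin, BaseEstimator):
    """Shared fitted-attribute plumbing for the two SFS search modes."""

    def __init__(
        self,
        n_neighbors: int = 10,
        cv: int = 5,
        features_per_channel: int = 1,
        channel_names: list[str] | None = None,
        cv_random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.cv = cv
        self.features_per_channel = features_per_channel
        self.channel_names = channel_names
        self.cv_random_state = cv_random_state

    def _names(self, n_channels: int) -> list[str]:
        if self.channel_names is not None:
            if len(self.channel_names) != n_channels:
                raise ConfigError("channel_names length != channel count")
            return list(self.channel_names)
        return [str(i + 1) for i in range(n_channels)]

    def _eval_subset(self, X, y, subset) -> float:
        cols = _subset_columns(subset, self.features_per_channel)
        return _pooled_knn_cv(
            X[:, cols], y, self.n_neighbors, self.cv, self.cv_random_state
        ).accuracy

    def _get_support_mask(self):
        check_is_fitted(self)
        f = self.features_per_channel
        mask = np.zeros(self.n_features_in_, dtype=bool)
        for c in self.optimal_channel_indices_:
            mask[c * f : (c + 1) * f] = True
        return mask


class ReliefFSFS(_BaseSFS):
    """The canonical method: subsets are prefixes of the ReliefF ranking.

    ``fit`` computes the ranking once, evaluates KNN CV accuracy for every
    prefix size 1..n_channels and keeps the smallest size attaining the
    maximum. ``transform`` keeps the optimal channels' columns.

    Attributes
    ----------
    ranking_ : ChannelRanking
    accuracy_by_size_ : accuracy for subset sizes 1..n_channels.
    optimal_size_ : smallest size attaining max accuracy.
    optimal_channel_indices_ : 0-based indices, ranking order.
    optimal_channels_ : channel names, ranking order.
    """

    def __init__(
        self,
        m_iter: int = 80,
        k_nn: int = 10,
        n_neighbors: int = 10,
        cv: int = 5,
        features_per_channel: int = 1,
        channel_names: list[str] | None = None,
        random_state: int = 0,
        cv_random_state: int = 0,
    ):
        super().__init__(
            n_neighbors=n_neighbors,
            cv=cv,
            features_per_channel=features_per_channel,
            channel_names=channel_names,
            cv_random_state=cv_random_state,
        )
        self.m_iter = m_iter
        self.k_nn = k_nn
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        weighter = ReliefFWeighting(
            m_iter=self.m_iter,
            k_nn=self.k_nn,
            features_per_channel=self.features_per_channel,
            random_state=self.random_state,
        ).fit(X, y)
        n_ch = len(weighter.weights_)
        names = self._names(n_ch)
        self.ranking_ = weighter.ranking(names)
        acc = np.empty(n_ch)
        for size in range(1, n_ch + 1):
            acc[size - 1] = self._eval_subset(X, y, self.ranking_.order[:size])
        self.accuracy_by_size_ = acc
        self.optimal_size_ = _optimal_size(acc)
        self.optimal_channel_indices_ = self.ranking_.order[: self.optimal_size_].copy()
        self.optimal_channels_ = [names[i] for i in self.optimal_channel_indices_]
        return self


class GreedySFS(_BaseSFS):
    """Classical accuracy-greedy sequential forward selection over channels.

    At each step the channel whose addition maximises CV accuracy joins the
    subset (ties: lower channel index). Kept as a comparison mode; the
    weight-ordered search above is the method proper.
    """

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        f = self.features_per_channel
        if X.shape[1] % f:
            raise ConfigError("columns not divisible by features_per_channel")
        n_ch = X.shape[1] // f
        names = self._names(n_ch)
        chosen: list[int] = []
        acc = np.empty(n_ch)
        remaining = list(range(n_ch))
        for size in range(1, n_ch + 1):
            best_c, best_a = None, -np.inf
            for c in remaining:
                a = self._eval_subset(X, y, chosen + [c])
                if a > best_a:  # strict: first (lowest-index) winner kept on ties
                    best_c, best_a = c, a
            chosen.append(best_c)
            remaining.remove(best_c)
            acc[size - 1] = best_a
        order = np.array(chosen)
        self.ranking_ = ChannelRanking(
            weights=np.zeros(n_ch),
            order=order,
            feature_weights=np.zeros(n_ch * f),
            channel_names=names,
        )
        self.accuracy_by_size_ = acc
        self.optimal_size_ = _optimal_size(acc)
        self.optimal_channel_indices_ = order[: self.optimal_size_].copy()
        self.optimal_channels_ = [names[i] for i in self.optimal_channel_indices_]
        return self


# ---------------------------------------------------------------------------
# FeatureMatrix-level wrappers
# ---------------------------------------------------------------------------

def relieff_weights(fm: FeatureMatrix, p: ReliefFParams | None = None) -> ChannelRanking:
    """Per-channel ReliefF weights of a feature matrix, sorted descending."""
    p = p or ReliefFParams()
    est = ReliefFWeighting(
        m_iter=p.m_iter,
        k_nn=p.k_nn,
        features_per_channel=fm.features_per_channel,
        random_state=p.seed,
    ).fit(fm.values, fm.labels)
    return est.ranking(fm.channel_names)


def knn_cv_accuracy(
    fm: FeatureMatrix, channel_subset, ep: EvalParams | None = None
) -> float:
    """Pooled stratified-CV KNN accuracy of a channel subset (0-based indices)."""
    ep = ep or EvalParams()
    subset = list(channel_subset)
    if not subset:
        raise DataError("channel subset must be non-empty")
    cols = _subset_columns(subset, fm.features_per_channel)
    return _pooled_knn_cv(
        fm.values[:, cols], fm.labels, ep.K, ep.folds, ep.seed
    ).accuracy


def _run_sfs(est: _BaseSFS, fm: FeatureMatrix) -> SelectionResult:
    est.fit(fm.values, fm.labels)
    return SelectionResult(
        ranking=est.ranking_,
        accuracy_by_size=est.accuracy_by_size_,
        optimal_size=est.optimal_size_,
        optimal_channels=est.optimal_channels_,
    )


def relieff_sfs(
    fm: FeatureMatrix,
    p: ReliefFParams | None = None,
    ep: EvalParams | None = None,
) -> SelectionResult:
    """Weight-ordered subset search: rank channels by ReliefF, score prefixes."""
    p = p or ReliefFParams()
    ep = ep or EvalParams()
    est = ReliefFSFS(
        m_iter=p.m_iter,
        k_nn=p.k_nn,
        n_neighbors=ep.K,
        cv=ep.folds,
        features_per_channel=fm.features_per_channel,
        channel_names=fm.channel_names,
        random_state=p.seed,
        cv_random_state=ep.seed,
    )
    return _run_sfs(est, fm)


def greedy_sfs(fm: FeatureMatrix, ep: EvalParams | None = None) -> SelectionResult:
    """Classical accuracy-greedy SFS over channels."""
    ep = ep or EvalParams()
    est = GreedySFS(
        n_neighbors=ep.K,
        cv=ep.folds,
        features_per_channel=fm.features_per_channel,
        channel_names=fm.channel_names,
        cv_random_state=ep.seed,
    )
    return _run_sfs(est, fm)
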