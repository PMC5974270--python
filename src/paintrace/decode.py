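"""SVM decoding trajectories and permutation chance levels.

A polynomial-kernel support vector machine (decision function
``y = sum_i alpha_i K(x, x_i) + b``, solved by the libsvm SMO dual solver)
is evaluated at every time bin of a cumulative feature series with stratified
5-fold cross-validation, each fold holding out ~20% of trials. The procedure
repeats over Monte-Carlo re-partitions (mean +/- SEM reported), and a
label-permutation control (500 shuffles by default) provides the chance
level that anchors the dynamic range for onset detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureSeries

__all__ = [
    "SVMSpec",
    "DecodingTrajectory",
    "ChanceLevel",
    "fit_svm",
    "decode_trajectory",
    "chance_level",
]


@dataclass(frozen=True)
class SVMSpec:
    """Polynomial-kernel SVM hyperparameters.

    ``standardize`` z-scales each feature using training-fold statistics
    only, which keeps the polynomial kernel well conditioned when spike
    counts and band powers mix on very different scales.
    """

    degree: int = 3
    box_constraint: float = 1.0
    coef0: float = 1.0
    standardize: bool = True

    def __post_init__(self):
        if self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.box_constraint <= 0:
            raise ValueError("box constraint must be positive")

    def build(self):
        svc = SVC(kernel="poly", degree=self.degree, C=self.box_constraint, coef0=self.coef0, gamma="scale")
        if self.standardize:
            return Pipeline([("scale", StandardScaler()), ("svm", svc)])
        return svc


def fit_svm(X: np.ndarray, y: np.ndarray, spec: SVMSpec = SVMSpec()):
    """Fit the polynomial-kernel SVM; deterministic given data and spec."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be trials x features matching y")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if np.unique(y).size != 2:
        raise ValueError("need exactly two classes")
    return spec.build().fit(X, y)


@dataclass
class ChanceLevel:
    """Mean and SD of shuffled-label decoding accuracy."""

    value: float
    sd: float
    n_shuffle: int


@dataclass
class DecodingTrajectory:
    """Time-resolved cross-validated accuracy with its permutation control.

    ``per_run_acc`` is n_mc x n_times; mean and SEM (SD / sqrt(n_mc)) are
    over Monte-Carlo repartitions. ``peak_time`` is the earliest argmax.
    """

    times: np.ndarray
    mean_acc: np.ndarray
    sem_acc: np.ndarray
    n_mc: int
    folds: int
    per_run_acc: np.ndarray | None = None
    chance: float | None = None
    chance_sd: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def peak_acc(self) -> float:
        return float(self.mean_acc.max())

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.mean_acc))])

    def with_chance(self, chance: ChanceLevel) -> "DecodingTrajectory":
        self.chance = chance.value
        self.chance_sd = chance.sd
        return self


def _cv_accuracy(X: np.ndarray, y: np.ndarray, spec: SVMSpec, splits) -> float:
    acc = 0.0
    for train, test in splits:
        clf = spec.build().fit(X[train], y[train])
        acc += float(np.mean(clf.predict(X[test]) == y[test]))
    return acc / len(splits)


def _check_labels(y: np.ndarray, folds: int):
    vals, counts = np.unique(y, return_counts=True)
    if vals.size != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} trials per class for {folds}-fold CV")


def decode_trajectory(
    fs: FeatureSeries,
    labels: np.ndarray | None = None,
    spec: SVMSpec = SVMSpec(),
    n_mc: int = 100,
    folds: int = 5,
    seed: int | None = 0,
    eval_bins=None,
) -> DecodingTrajectory:
    """Cross-validated accuracy at each time bin over Monte-Carlo runs.

    Each run draws a fresh stratified fold partition, reused across all time
    bins of that run so the trajectory's shape is not blurred by partition
    noise. Seeds come from one master ``SeedSequence``: run i sees the same
    substream regardless of ``n_mc``. ``eval_bins`` restricts evaluation to
    a subset of 1-based bins (an int is a stride) for cheaper trajectories.
    """
    y = np.asarray(labels if labels is not None else fs.labels)
    if y is None or y.shape[0] != fs.n_trials:
        raise ValueError("labels missing or mismatched with feature trials")
    _check_labels(y, folds)

    if eval_bins is None:
        bins = np.arange(1, fs.n_bins + 1)
    elif np.isscalar(eval_bins):
        bins = np.arange(int(eval_bins), fs.n_bins + 1, int(eval_bins))
        if bins.size == 0 or bins[-1] != fs.n_bins:
            bins = np.append(bins, fs.n_bins)
    else:
        bins = np.asarray(eval_bins, dtype=int)

    ss = np.random.SeedSequence(seed)
    run_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_mc)]
    acc = np.empty((n_mc, bins.size))
    dummy = np.zeros((fs.n_trials, 1))
    for r, rs in enumerate(run_seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        splits = list(skf.split(dummy, y))
        for j, k in enumerate(bins):
            acc[r, j] = _cv_accuracy(fs.matrix_at(int(k)), y, spec, splits)

    mean = acc.mean(axis=0)
    sem = acc.std(axis=0, ddof=1) / np.sqrt(n_mc) if n_mc > 1 else np.zeros(bins.size)
    return DecodingTrajectory(
        times=fs.times[bins - 1],
        mean_acc=mean,
        sem_acc=sem,
        n_mc=n_mc,
        folds=folds,
        per_run_acc=acc,
        meta={"modality": fs.modality, "bins": bins, "spec": spec},
    )


def chance_level(
    fs: FeatureSeries,
    labels: np.ndarray | None = None,
    spec: SVMSpec = SVMSpec(),
    n_shuffle: int = 500,
    folds: int = 5,
    seed: int | None = 0,
    bin_index: int | None = None,
) -> ChanceLevel:
    """Permutation chance level of the decoder.

    Class labels are randomly permuted across trials; each shuffle runs one
    stratified cross-validation on the (untouched) feature matrix at the
    requested bin (final bin by default). Returns the mean shuffled accuracy
    and its across-shuffle SD — close to 50% for balanced classes.
    """
    y = np.asarray(labels if labels is not None else fs.labels)
    if y is None or y.shape[0] != fs.n_trials:
        raise ValueError("labels missing or mismatched with feature trials")
    _check_labels(y, folds)
    k = fs.n_bins if bin_index is None else bin_index
    X = fs.matrix_at(k)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    accs = np.empty(n_shuffle)
    dummy = np.zeros((fs.n_trials, 1))
    for s in range(n_shuffle):
        perm = rng.permutation(fs.n_trials)
        yp = y[perm]
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
        splits = list(skf.split(dummy, yp))
        accs[s] = _cv_accuracy(X, yp, spec, splits)
    return ChanceLevel(value=float(accs.mean()), sd=float(accs.std(ddof=1)), n_shuffle=n_shuffle)
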