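"""Multivariate pattern classification of tumour grade from connectivity features.

Three-step procedure: (1) per-fold feature ranking by the absolute
Kendall tau-b correlation between each feature and the binary group label
("discriminative power"), (2) consensus feature selection — features in
the top-k ranking of *every* cross-validation training fold — followed by
a linear support vector machine evaluated by leave-one-out
cross-validation, and (3) a permutation null for the overall accuracy
obtained by rerunning the whole pipeline under label shuffles.

Specificity is the accuracy on the first class (the slow-growing-glioma
role), sensitivity the accuracy on the second; overall accuracy is their
mean, so it is balanced even though group sizes may differ after QC.

Kendall tau-b against a binary label is computed from pooled midranks via
the Mann-Whitney identity C - D = 2U - nA*nB, which lets the expensive
ranking be shared across label permutations (ranks do not depend on the
labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 200
DEFAULT_N_PERM = 10_000


@dataclass
class LabeledFeatureSet:
    """Subjects x features matrix with binary group labels."""

    features: np.ndarray
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    index_map: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be subjects x features")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("one label per subject required")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        classes = list(dict.fromkeys(self.labels.tolist()))  # first-appearance order
        if len(classes) != 2:
            raise ValueError(f"exactly two label values required, got {classes}")
        self.classes: tuple = (classes[0], classes[1])
        if not self.subject_ids:
            self.subject_ids = [f"S{i:03d}" for i in range(self.features.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def y01(self) -> np.ndarray:
        """Labels coded 0 (class A) / 1 (class B)."""
        return (self.labels == self.classes[1]).astype(int)


@dataclass
class ConsensusSelection:
    per_fold_rankings: list[np.ndarray]
    k: int
    consensus: np.ndarray

    def __post_init__(self) -> None:
        self.consensus = np.asarray(self.consensus, dtype=int)


@dataclass
class ClassificationResult:
    per_subject_prediction: np.ndarray
    specificity: float
    sensitivity: float
    overall_accuracy: float
    classes: tuple
    permutation_p: float | None = None
    n_permutations: int = 0
    null_accuracies: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Kendall tau-b discriminative power


def _tie_pair_counts(x: np.ndarray) -> np.ndarray:
    """Per column: number of (i<j) pairs tied in x (sum over groups of t(t-1)/2)."""
    rmax = rankdata(x, method="max", axis=0)
    rmin = rankdata(x, method="min", axis=0)
    return (rmax - rmin).sum(axis=0) / 2.0


def _powers_from_ranks(
    ranks: np.ndarray, tx: np.ndarray, y01: np.ndarray
) -> np.ndarray:
    """|tau-b| for every column given pooled midranks and tie-pair counts."""
    n = y01.shape[0]
    nb = int(y01.sum())
    na = n - nb
    n0 = n * (n - 1) / 2.0
    ty = na * (na - 1) / 2.0 + nb * (nb - 1) / 2.0
    u = y01 @ ranks - nb * (nb + 1) / 2.0
    num = 2.0 * u - na * nb
    denom = np.sqrt(np.maximum(n0 - tx, 0.0) * max(n0 - ty, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0, num / denom, 0.0)
    return np.abs(tau)


def kendall_power(feature_column: np.ndarray, labels: np.ndarray) -> float:
    """Absolute Kendall tau-b between one feature and binary labels, in [0, 1].

    A constant feature has power 0 (all pairs tied).
    """
    x = np.asarray(feature_column, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if x.shape[0] < 2 or classes.size != 2:
        raise ValueError("need >= 2 subjects with both labels present")
    y01 = (labels == classes[1]).astype(int)
    ranks = rankdata(x, axis=0)
    tx = _tie_pair_counts(x)
    return float(_powers_from_ranks(ranks, tx, y01)[0])


def discriminative_powers(features: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Vectorized |tau-b| of every feature column against the binary labels."""
    ranks = rankdata(features, axis=0)
    tx = _tie_pair_counts(features)
    return _powers_from_ranks(ranks, tx, y01)


def _top_k(powers: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest powers; ties broken by ascending feature index."""
    order = np.lexsort((np.arange(powers.size), -powers))
    return order[:k]


def rank_features(train: LabeledFeatureSet, k: int) -> np.ndarray:
    """Top-k feature indices by discriminative power on the training set."""
    if k > train.n_features:
        raise ValueError(f"k={k} exceeds feature count {train.n_features}")
    powers = discriminative_powers(train.features, train.y01)
    return _top_k(powers, k)


# ---------------------------------------------------------------------------
# folds and consensus selection


def make_folds(
    labels: np.ndarray,
    cv: Literal["loo", "tenfold"] = "loo",
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) splits: leave-one-out or stratified ten-fold."""
    n = labels.shape[0]
    if cv == "loo":
        idx = np.arange(n)
        return [(np.delete(idx, i), np.array([i])) for i in range(n)]
    if cv == "tenfold":
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(n), labels)]
    raise ValueError(f"unknown cv mode {cv!r}")


class _RankCache:
    """Per-fold pooled midranks of the training features, shared across label
    permutations (feature ranks are label-free)."""

    def __init__(self, features: np.ndarray,
                 folds: Sequence[tuple[np.ndarray, np.ndarray]]):
        self.folds = list(folds)
        self.ranks = []
        self.tx = []
        for tr, _ in self.folds:
            x = features[tr]
            self.ranks.append(rankdata(x, axis=0))
            self.tx.append(_tie_pair_counts(x))

    def consensus(self, y01: np.ndarray, k: int) -> ConsensusSelection:
        p = self.ranks[0].shape[1]
        counts = np.zeros(p, dtype=int)
        rankings = []
        for (tr, _), ranks, tx in zip(self.folds, self.ranks, self.tx):
            powers = _powers_from_ranks(ranks, tx, y01[tr])
            top = _top_k(powers, k)
            rankings.append(top)
            counts[top] += 1
        consensus = np.where(counts == len(self.folds))[0]
        return ConsensusSelection(rankings, k, consensus)


def consensus_features(
    dataset: LabeledFeatureSet,
    k: int = DEFAULT_TOP_K,
    cv: Literal["loo", "tenfold"] = "loo",
    seed: int = 0,
) -> ConsensusSelection:
    """Features appearing in the top-k ranking of every training fold.

    Ranking is computed inside each fold's training subjects only, so the
    held-out subject never influences its own fold's selection.
    """
    if dataset.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if k > dataset.n_features:
        raise ValueError(f"k={k} exceeds feature count {dataset.n_features}")
    folds = make_folds(dataset.labels, cv, seed)
    sel = _RankCache(dataset.features, folds).consensus(dataset.y01, k)
    if sel.consensus.size == 0:
        logger.warning("consensus feature set is empty (k=%d, %d folds)",
                       k, len(folds))
    return sel


# ---------------------------------------------------------------------------
# classification


def _loocv_accuracy(
    features: np.ndarray,
    y01: np.ndarray,
    fold_features: Sequence[np.ndarray],
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    c: float,
) -> tuple[np.ndarray, float, float, float]:
    pred = np.empty(y01.shape[0], dtype=int)
    for (tr, te), idx in zip(folds, fold_features):
        if len(np.unique(y01[tr])) < 2:
            raise ValueError("a training fold is missing one class")
        x = features[:, idx]
        clf = SVC(kernel="linear", C=c)
        clf.fit(x[tr], y01[tr])
        pred[te] = clf.predict(x[te])
    mask_a = y01 == 0
    specificity = float((pred[mask_a] == 0).mean())
    sensitivity = float((pred[~mask_a] == 1).mean())
    overall = (specificity + sensitivity) / 2.0
    return pred, specificity, sensitivity, overall


def _fold_feature_sets(
    selection: ConsensusSelection,
    n_folds: int,
    feature_mode: Literal["per_fold", "consensus"],
) -> list[np.ndarray]:
    if feature_mode == "per_fold":
        if len(selection.per_fold_rankings) != n_folds:
            raise ValueError("selection fold count does not match the CV folds")
        return list(selection.per_fold_rankings)
    if feature_mode == "consensus":
        if selection.consensus.size == 0:
            raise ValueError("consensus feature set is empty")
        return [selection.consensus] * n_folds
    raise ValueError(f"unknown feature_mode {feature_mode!r}")


def loocv_classify(
    dataset: LabeledFeatureSet,
    selection: ConsensusSelection,
    c: float = 1.0,
    cv: Literal["loo", "tenfold"] = "loo",
    seed: int = 0,
    feature_mode: Literal["per_fold", "consensus"] = "per_fold",
) -> ClassificationResult:
    """Linear SVM on the selected features, evaluated by cross-validation.

    In the default ``per_fold`` mode each fold's classifier uses that
    fold's own top-k ranking, so the held-out subject never influences the
    features it is classified with and chance-level data yields
    chance-level accuracy.  ``consensus`` mode instead fixes the consensus
    intersection for every fold; because the intersection is computed
    across all folds it carries a selection-bias optimism on null data and
    is only interpretable against a permutation null run in the same mode.

    Specificity = accuracy on class A, sensitivity = accuracy on class B,
    overall accuracy = their mean.
    """
    folds = make_folds(dataset.labels, cv, seed)
    fold_feats = _fold_feature_sets(selection, len(folds), feature_mode)
    pred01, spec, sens, overall = _loocv_accuracy(
        dataset.features, dataset.y01, fold_feats, folds, c
    )
    pred = np.asarray(dataset.classes, dtype=object)[pred01]
    return ClassificationResult(pred, spec, sens, overall, dataset.classes)


def classify_pipeline(
    dataset: LabeledFeatureSet,
    k: int = DEFAULT_TOP_K,
    c: float = 1.0,
    cv: Literal["loo", "tenfold"] = "loo",
    seed: int = 0,
    feature_mode: Literal["per_fold", "consensus"] = "per_fold",
) -> tuple[ConsensusSelection, ClassificationResult]:
    """Consensus selection followed by cross-validated classification."""
    sel = consensus_features(dataset, k, cv, seed)
    return sel, loocv_classify(dataset, sel, c, cv, seed, feature_mode)


def permutation_test_accuracy(
    dataset: LabeledFeatureSet,
    k: int = DEFAULT_TOP_K,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    c: float = 1.0,
    nested: bool = True,
    cv: Literal["loo", "tenfold"] = "loo",
    feature_mode: Literal["per_fold", "consensus"] = "per_fold",
) -> ClassificationResult:
    """Permutation null for the overall accuracy.

    Each permutation shuffles the group labels once and reruns the
    classification; in ``nested`` mode (default) the per-fold feature
    ranking (and consensus selection) is refit inside the permutation,
    keeping the null exchangeable with the observed statistic.  With
    ``nested=False`` the observed feature sets are reused.
    p = (1 + #{null >= observed}) / (1 + n_perm), so p is never exactly
    zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    folds = make_folds(dataset.labels, cv, seed)
    cache = _RankCache(dataset.features, folds)
    y01 = dataset.y01

    sel = cache.consensus(y01, k)
    obs_feats = _fold_feature_sets(sel, len(folds), feature_mode)
    pred01, spec, sens, observed = _loocv_accuracy(
        dataset.features, y01, obs_feats, folds, c
    )

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        yb = rng.permutation(y01)
        if nested:
            sel_b = cache.consensus(yb, k)
            if feature_mode == "consensus" and sel_b.consensus.size == 0:
                # an empty consensus cannot classify; fall back to the
                # pooled top-k ranking of this permutation
                fold_feats = [
                    _top_k(discriminative_powers(dataset.features, yb), k)
                ] * len(folds)
            else:
                fold_feats = _fold_feature_sets(sel_b, len(folds), feature_mode)
        else:
            fold_feats = obs_feats
        try:
            _, _, _, acc = _loocv_accuracy(dataset.features, yb, fold_feats,
                                           folds, c)
        except ValueError:
            # a permuted training fold lost a class (only possible at tiny n)
            acc = np.nan
        null[b] = acc
    valid = null[np.isfinite(null)]
    p = (1.0 + float((valid >= observed).sum())) / (1.0 + valid.size)
    pred = np.asarray(dataset.classes, dtype=object)[pred01]
    return ClassificationResult(
        pred, spec, sens, observed, dataset.classes,
        permutation_p=p, n_permutations=int(valid.size), null_accuracies=null,
    )
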