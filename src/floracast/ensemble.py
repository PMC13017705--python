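"""Five-learner suitability ensemble with AUC screening and max-TSS binarization.

Each learner maps a covariate vector to a suitability score in [0, 1]. A
species' ensemble is the AUC-weighted mean of the learners that clear the
cross-validated AUC cutoff; the binarization threshold maximizes the true
skill statistic (sensitivity + specificity - 1) on the training scores.

Learner kinds
-------------
``envelope``
    Percentile box ([p5, p95] per covariate) of the presences; suitability is
    the fraction of covariates inside the box.
``mahalanobis``
    exp(-D^2 / 2) with D the Mahalanobis distance to the presence mean in
    z-scored covariate space (regularized covariance).
``logistic2``
    Maximum-likelihood logistic regression on linear plus quadratic terms.
``knn``
    Distance-weighted fraction of presences among the k nearest training
    points in z-scored covariate space.
``boost_stumps``
    Gradient-boosted depth-1 stumps on logistic loss, output through the
    logistic function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import FitFailureError, UndefinedAUCError, UnmodelableSpeciesError
from .prep import ModelingDataset

logger = logging.getLogger(__name__)

LEARNER_KINDS = ("envelope", "mahalanobis", "logistic2", "knn", "boost_stumps")

_EPS = 1e-12


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class Learner:
    """Base class: fit on (X, y) with y=1 presences, y=0 background."""

    kind: str = "base"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Learner":
        raise NotImplementedError

    def predict_suitability(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def to_params(self) -> dict:
        raise NotImplementedError

    @classmethod
    def from_params(cls, params: dict) -> "Learner":
        raise NotImplementedError


class EnvelopeLearner(Learner):
    kind = "envelope"

    def __init__(self, lower_pct: float = 5.0, upper_pct: float = 95.0):
        self.lower_pct = lower_pct
        self.upper_pct = upper_pct
        self.lo_: np.ndarray | None = None
        self.hi_: np.ndarray | None = None

    def fit(self, X, y):
        P = X[y == 1]
        self.lo_ = np.percentile(P, self.lower_pct, axis=0)
        self.hi_ = np.percentile(P, self.upper_pct, axis=0)
        return self

    def predict_suitability(self, X):
        inside = (X >= self.lo_) & (X <= self.hi_)
        return inside.mean(axis=1)

    def to_params(self):
        return {
            "kind": self.kind,
            "lower_pct": self.lower_pct,
            "upper_pct": self.upper_pct,
            "lo": self.lo_.tolist(),
            "hi": self.hi_.tolist(),
        }

    @classmethod
    def from_params(cls, params):
        obj = cls(params["lower_pct"], params["upper_pct"])
        obj.lo_ = np.asarray(params["lo"], dtype=float)
        obj.hi_ = np.asarray(params["hi"], dtype=float)
        return obj


class MahalanobisLearner(Learner):
    kind = "mahalanobis"

    def __init__(self, regularization: float = 1e-6):
        self.regularization = regularization
        self.z_mean_: np.ndarray | None = None
        self.z_sd_: np.ndarray | None = None
        self.center_: np.ndarray | None = None
        self.precision_: np.ndarray | None = None

    def fit(self, X, y):
        self.z_mean_ = X.mean(axis=0)
        self.z_sd_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        P = (X[y == 1] - self.z_mean_) / self.z_sd_
        self.center_ = P.mean(axis=0)
        cov = np.cov(P, rowvar=False)
        cov = np.atleast_2d(cov) + self.regularization * np.eye(P.shape[1])
        try:
            self.precision_ = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - regularized
            raise FitFailureError(f"singular covariance: {exc}") from exc
        return self

    def predict_suitability(self, X):
        Z = (X - self.z_mean_) / self.z_sd_
        d = Z - self.center_
        d2 = np.einsum("ij,jk,ik->i", d, self.precision_, d)
        return np.exp(-0.5 * np.maximum(d2, 0.0))

    def to_params(self):
        return {
            "kind": self.kind,
            "regularization": self.regularization,
            "z_mean": self.z_mean_.tolist(),
            "z_sd": self.z_sd_.tolist(),
            "center": self.center_.tolist(),
            "precision": self.precision_.tolist(),
        }

    @classmethod
    def from_params(cls, params):
        obj = cls(params["regularization"])
        obj.z_mean_ = np.asarray(params["z_mean"], dtype=float)
        obj.z_sd_ = np.asarray(params["z_sd"], dtype=float)
        obj.center_ = np.asarray(params["center"], dtype=float)
        obj.precision_ = np.asarray(params["precision"], dtype=float)
        return obj


class Logistic2Learner(Learner):
    """Logistic regression on [x, x^2] features, unpenalized MLE."""

    kind = "logistic2"

    def __init__(self, max_iter: int = 2000):
        self.max_iter = max_iter
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None

    @staticmethod
    def _features(X):
        return np.hstack([X, X**2])

    def fit(self, X, y):
        F = self._features(X)
        clf = LogisticRegression(penalty=None, max_iter=self.max_iter, solver="lbfgs")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separable data never converges fully
            clf.fit(F, y)
        self.coef_ = clf.coef_.ravel()
        self.intercept_ = float(clf.intercept_[0])
        return self

    def predict_suitability(self, X):
        F = self._features(X)
        return _sigmoid(F @ self.coef_ + self.intercept_)

    def to_params(self):
        return {
            "kind": self.kind,
            "max_iter": self.max_iter,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_params(cls, params):
        obj = cls(params["max_iter"])
        obj.coef_ = np.asarray(params["coef"], dtype=float)
        obj.intercept_ = float(params["intercept"])
        return obj


class KnnLearner(Learner):
    kind = "knn"

    def __init__(self, k: int | None = None):
        self.k = k
        self.z_mean_: np.ndarray | None = None
        self.z_sd_: np.ndarray | None = None
        self.train_X_: np.ndarray | None = None
        self.train_y_: np.ndarray | None = None
        self.k_: int | None = None
        self._tree: cKDTree | None = None

    def fit(self, X, y):
        self.z_mean_ = X.mean(axis=0)
        self.z_sd_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.train_X_ = (X - self.z_mean_) / self.z_sd_
        self.train_y_ = np.asarray(y, dtype=float)
        n_presence = int((y == 1).sum())
        self.k_ = self.k if self.k is not None else min(10, n_presence)
        self.k_ = max(1, min(self.k_, len(y)))
        self._tree = cKDTree(self.train_X_)
        return self

    def predict_suitability(self, X):
        if self._tree is None:
            self._tree = cKDTree(self.train_X_)
        Z = (X - self.z_mean_) / self.z_sd_
        dist, idx = self._tree.query(Z, k=self.k_)
        dist = np.atleast_2d(dist.reshape(len(Z), -1))
        idx = np.atleast_2d(idx.reshape(len(Z), -1))
        w = 1.0 / (dist + _EPS)
        return (w * self.train_y_[idx]).sum(axis=1) / w.sum(axis=1)

    def to_params(self):
        return {
            "kind": self.kind,
            "k": self.k_,
            "z_mean": self.z_mean_.tolist(),
            "z_sd": self.z_sd_.tolist(),
            "train_X": self.train_X_.tolist(),
            "train_y": self.train_y_.tolist(),
        }

    @classmethod
    def from_params(cls, params):
        obj = cls(params["k"])
        obj.k_ = params["k"]
        obj.z_mean_ = np.asarray(params["z_mean"], dtype=float)
        obj.z_sd_ = np.asarray(params["z_sd"], dtype=float)
        obj.train_X_ = np.asarray(params["train_X"], dtype=float)
        obj.train_y_ = np.asarray(params["train_y"], dtype=float)
        return obj


class BoostStumpsLearner(Learner):
    """Gradient-boosted depth-1 stumps, stored as explicit stump parameters."""

    kind = "boost_stumps"

    def __init__(self, n_stumps: int = 100, learning_rate: float = 0.1, seed: int | None = 0):
        self.n_stumps = n_stumps
        self.learning_rate = learning_rate
        self.seed = seed
        self.intercept_: float | None = None
        # rows: (feature, threshold, left_value, right_value); constant stumps
        # use feature -1 with the value in left_value.
        self.stumps_: np.ndarray | None = None

    def fit(self, X, y):
        clf = GradientBoostingClassifier(
            max_depth=1,
            n_estimators=self.n_stumps,
            learning_rate=self.learning_rate,
            random_state=self.seed,
        )
        clf.fit(X, y)
        p = float(np.clip(y.mean(), 1e-9, 1 - 1e-9))
        self.intercept_ = float(np.log(p / (1 - p)))
        rows = []
        for est in clf.estimators_.ravel():
            t = est.tree_
            if t.node_count == 1:
                rows.append((-1, 0.0, float(t.value[0, 0, 0]), 0.0))
            else:
                rows.append(
                    (
                        int(t.feature[0]),
                        float(t.threshold[0]),
                        float(t.value[t.children_left[0], 0, 0]),
                        float(t.value[t.children_right[0], 0, 0]),
                    )
                )
        self.stumps_ = np.asarray(rows, dtype=float)
        return self

    def _raw(self, X):
        raw = np.full(len(X), self.intercept_)
        for feat, thr, left, right in self.stumps_:
            if feat < 0:
                raw += self.learning_rate * left
            else:
                raw += self.learning_rate * np.where(X[:, int(feat)] <= thr, left, right)
        return raw

    def predict_suitability(self, X):
        return _sigmoid(self._raw(X))

    def to_params(self):
        return {
            "kind": self.kind,
            "n_stumps": self.n_stumps,
            "learning_rate": self.learning_rate,
            "intercept": self.intercept_,
            "stumps": self.stumps_.tolist(),
        }

    @classmethod
    def from_params(cls, params):
        obj = cls(params["n_stumps"], params["learning_rate"])
        obj.intercept_ = float(params["intercept"])
        obj.stumps_ = np.asarray(params["stumps"], dtype=float)
        return obj


_LEARNER_CLASSES = {
    c.kind: c
    for c in (
        EnvelopeLearner,
        MahalanobisLearner,
        Logistic2Learner,
        KnnLearner,
        BoostStumpsLearner,
    )
}


def learner_from_params(params: dict) -> Learner:
    return _LEARNER_CLASSES[params["kind"]].from_params(params)


def fit_learner(kind: str, dataset: ModelingDataset, seed: int | None = 0) -> Learner:
    """Fit one learner kind on a modelling dataset.

    Raises :class:`FitFailureError` if the fit cannot be completed; callers
    exclude the learner and continue.
    """
    if kind not in _LEARNER_CLASSES:
        raise ValueError(f"unknown learner kind {kind!r}; choose from {LEARNER_KINDS}")
    if len(dataset.presence_cells) < 2 or len(dataset.background_cells) < 2:
        raise FitFailureError(f"{dataset.species_id}: need >=2 presence and background cells")
    learner = (
        BoostStumpsLearner(seed=seed) if kind == "boost_stumps" else _LEARNER_CLASSES[kind]()
    )
    try:
        return learner.fit(dataset.X, dataset.y)
    except FitFailureError:
        raise
    except Exception as exc:
        raise FitFailureError(f"{dataset.species_id}/{kind}: {exc}") from exc


def auc(scores_presence, scores_background) -> float:
    """Mann-Whitney AUC: P(presence score > background score) + 0.5 P(tie).

    Computed with the rank-sum identity; ties receive average ranks.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise UndefinedAUCError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def cross_validated_auc(
    kind: str,
    dataset: ModelingDataset,
    n_folds: int = 5,
    seed: int | None = 0,
) -> float:
    """Mean held-out AUC over stratified k-folds of presence + background cells.

    The fold count is reduced (with a warning) when either class has fewer
    members than ``n_folds``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    X, y = dataset.X, dataset.y
    min_class = int(min((y == 1).sum(), (y == 0).sum()))
    folds = min(n_folds, min_class)
    if folds < n_folds:
        logger.warning(
            "%s/%s: reducing folds %d -> %d (class sizes)",
            dataset.species_id,
            kind,
            n_folds,
            folds,
        )
    if folds < 2:
        raise FitFailureError(f"{dataset.species_id}: too few cells for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for train_idx, test_idx in skf.split(X, y):
        if kind == "boost_stumps":
            learner = BoostStumpsLearner(seed=seed)
        else:
            learner = _LEARNER_CLASSES[kind]()
        learner.fit(X[train_idx], y[train_idx])
        scores = learner.predict_suitability(X[test_idx])
        y_test = y[test_idx]
        fold_aucs.append(auc(scores[y_test == 1], scores[y_test == 0]))
    return float(np.mean(fold_aucs))


@dataclass
class EnsembleModel:
    """AUC-weighted combination of the learners that cleared the cutoff."""

    species_id: str
    learners: dict[str, Learner]
    auc_scores: dict[str, float]
    weights: dict[str, float]
    auc_cutoff: float
    covariate_names: list[str]
    train_min: np.ndarray
    train_max: np.ndarray
    threshold_tss: float | None = None
    version: str = field(default="1", repr=False)

    def predict(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Ensemble suitability in [0, 1] for covariate rows X.

        With ``clamp`` (default), covariates are clipped to the training range
        before prediction, so extrapolated cells take edge-of-range values.
        """
        X = np.asarray(X, dtype=float)
        if clamp:
            X = np.clip(X, self.train_min, self.train_max)
        out = np.zeros(len(X))
        for kind, w in self.weights.items():
            if w > 0:
                out += w * self.learners[kind].predict_suitability(X)
        return np.clip(out, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "species_id": self.species_id,
            "auc_scores": self.auc_scores,
            "weights": self.weights,
            "auc_cutoff": self.auc_cutoff,
            "covariate_names": self.covariate_names,
            "train_min": self.train_min.tolist(),
            "train_max": self.train_max.tolist(),
            "threshold_tss": self.threshold_tss,
            "learners": {k: l.to_params() for k, l in self.learners.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            species_id=d["species_id"],
            learners={k: learner_from_params(p) for k, p in d["learners"].items()},
            auc_scores={k: float(v) for k, v in d["auc_scores"].items()},
            weights={k: float(v) for k, v in d["weights"].items()},
            auc_cutoff=float(d["auc_cutoff"]),
            covariate_names=list(d["covariate_names"]),
            train_min=np.asarray(d["train_min"], dtype=float),
            train_max=np.asarray(d["train_max"], dtype=float),
            threshold_tss=None if d["threshold_tss"] is None else float(d["threshold_tss"]),
            version=str(d.get("version", "1")),
        )


def build_ensemble(
    species_id: str,
    learners: dict[str, Learner],
    aucs: dict[str, float],
    auc_cutoff: float = 0.7,
    covariate_names: list[str] | None = None,
    train_min: np.ndarray | None = None,
    train_max: np.ndarray | None = None,
) -> EnsembleModel:
    """Combine learners with weights proportional to max(AUC - 0.5, 0).

    Learners with AUC below ``auc_cutoff`` get weight 0. If no learner passes,
    the species is unmodelable and :class:`UnmodelableSpeciesError` is raised.
    """
    included = {k for k, a in aucs.items() if k in learners and a >= auc_cutoff}
    if not included:
        raise UnmodelableSpeciesError(
            f"{species_id}: no learner reached AUC {auc_cutoff} (best: "
            f"{max(aucs.values()) if aucs else float('nan'):.3f})"
        )
    raw = {k: max(aucs[k] - 0.5, 0.0) if k in included else 0.0 for k in learners}
    total = sum(raw.values())
    if total > 0:
        weights = {k: v / total for k, v in raw.items()}
    else:  # all included learners at chance level exactly: fall back to equal
        weights = {k: (1.0 / len(included) if k in included else 0.0) for k in learners}
    return EnsembleModel(
        species_id=species_id,
        learners=learners,
        auc_scores=dict(aucs),
        weights=weights,
        auc_cutoff=auc_cutoff,
        covariate_names=covariate_names or [],
        train_min=train_min if train_min is not None else np.array([]),
        train_max=train_max if train_max is not None else np.array([]),
    )


def tss_at_threshold(scores_presence, scores_background, threshold: float) -> float:
    """TSS = sensitivity + specificity - 1 with predicted-present = score >= t."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    sens = (sp >= threshold).mean()
    spec = (sb < threshold).mean()
    return float(sens + spec - 1.0)


def max_tss_threshold(scores_presence, scores_background) -> float:
    """Threshold maximizing TSS over observed scores and their midpoints.

    Ties are broken toward the lower threshold.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise UndefinedAUCError("both score sets must be non-empty")
    uniq = np.unique(np.concatenate([sp, sb]))
    candidates = np.unique(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]))
    best_t, best_tss = candidates[0], -np.inf
    for t in candidates:
        v = tss_at_threshold(sp, sb, t)
        if v > best_tss + 1e-15:
            best_t, best_tss = t, v
    return float(best_t)


def fit_species_ensemble(
    dataset: ModelingDataset,
    n_folds: int = 5,
    auc_cutoff: float = 0.7,
    kinds=LEARNER_KINDS,
    seed: int | None = 0,
) -> EnsembleModel:
    """Full per-species fit: CV-screen five learners, weight, set max-TSS cut."""
    learners: dict[str, Learner] = {}
    aucs: dict[str, float] = {}
    for kind in kinds:
        try:
            aucs[kind] = cross_validated_auc(kind, dataset, n_folds=n_folds, seed=seed)
            learners[kind] = fit_learner(kind, dataset, seed=seed)
        except FitFailureError as exc:
            logger.warning("learner excluded: %s", exc)
    model = build_ensemble(
        dataset.species_id,
        learners,
        aucs,
        auc_cutoff=auc_cutoff,
        covariate_names=dataset.covariate_names,
        train_min=dataset.X.min(axis=0),
        train_max=dataset.X.max(axis=0),
    )
    sp = model.predict(dataset.X_presence, clamp=False)
    sb = model.predict(dataset.X_background, clamp=False)
    model.threshold_tss = max_tss_threshold(sp, sb)
    return model
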