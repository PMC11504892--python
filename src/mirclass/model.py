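"""Classifiers for miRNA disease-association.

The headline method is a discrete Bayesian-network classifier with the naive
structure (the class is the sole parent of every attribute): numeric
attributes are supervisedly discretized at fit time (Fayyad-Irani MDL,
cutpoints frozen into the model), and each attribute gets a conditional
probability table estimated with a smoothing pseudo-count (default
alpha = 0.5).  Prediction multiplies the class prior by the per-attribute
likelihoods in log space.  A greedy structure search that may give each
attribute at most one extra parent is available behind
``structure="augmented"`` but is not the default.

Comparison baselines (naive Bayes with Gaussian numerics, batch decision
trees, random forest) sit behind the same :class:`TrainedClassifier`
contract; the tree and forest baselines delegate to scikit-learn.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigError, DomainError, SchemaError
from .infogain import _bin_indices, mdl_discretize
from .seqio import BINARY, NEGATIVE_LABEL, POSITIVE_LABEL, FeatureTable

__all__ = [
    "BayesNetClassifier",
    "TrainedClassifier",
    "PredictionResult",
    "fit_bayesnet",
    "fit_baseline",
    "save_model",
    "load_model",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = (
    "bayesnet",
    "naivebayes",
    "hoeffding_tree",
    "random_forest",
    "random_tree",
)

MODEL_FORMAT_VERSION = 1


def _infer_kinds(X: np.ndarray) -> list[str]:
    return [
        BINARY if X.shape[0] and np.all(np.isin(X[:, j], (0.0, 1.0))) else "numeric"
        for j in range(X.shape[1])
    ]


class BayesNetClassifier(ClassifierMixin, BaseEstimator):
    """Discrete Bayesian-network classifier (naive structure by default).

    Parameters
    ----------
    alpha : smoothing pseudo-count added per cell of every conditional
        probability table (and to the class prior).  Default 0.5.
    numeric_handling : ``"mdl"`` discretizes numeric attributes with the
        supervised Fayyad-Irani procedure at fit time; ``"gaussian"`` models
        them with per-class normal densities (the classic naive-Bayes
        treatment of numerics).
    structure : ``"naive"`` (class is the sole parent) or ``"augmented"``
        (greedy search may add at most one attribute parent per attribute
        when it improves a BIC-penalized conditional log-likelihood;
        requires ``numeric_handling="mdl"``).
    var_smoothing : variance floor for the Gaussian option, as a fraction of
        the largest feature variance.
    feature_kinds : optional explicit list of ``"numeric"``/``"binary"`` per
        column; by default a column is binary iff all its values are 0/1.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels.
    class_prior_ : smoothed class prior.
    cutpoints_ : per-feature cut lists (numeric, mdl mode).
    cpt_ : per-feature conditional probability tables; each row
        (class, [parent-bin]) sums to 1.
    parent_ : per-feature extra-parent index or None (augmented structure).
    """

    def __init__(
        self,
        alpha: float = 0.5,
        numeric_handling: str = "mdl",
        structure: str = "naive",
        var_smoothing: float = 1e-9,
        feature_kinds: Sequence[str] | None = None,
    ):
        self.alpha = alpha
        self.numeric_handling = numeric_handling
        self.structure = structure
        self.var_smoothing = var_smoothing
        self.feature_kinds = feature_kinds

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if self.numeric_handling not in ("mdl", "gaussian"):
            raise ConfigError(f"unknown numeric_handling {self.numeric_handling!r}")
        if self.structure not in ("naive", "augmented"):
            raise ConfigError(f"unknown structure {self.structure!r}")
        if self.structure == "augmented" and self.numeric_handling != "mdl":
            raise ConfigError('structure="augmented" requires numeric_handling="mdl"')
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise DomainError("X must be 2-D with one label per row")
        self.classes_, codes = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise DomainError("training set contains a single class")
        n, p = X.shape
        self.n_features_in_ = p
        kinds = (
            list(self.feature_kinds)
            if self.feature_kinds is not None
            else _infer_kinds(X)
        )
        if len(kinds) != p:
            raise DomainError("feature_kinds length does not match feature count")
        self.feature_kinds_ = kinds

        class_counts = np.bincount(codes, minlength=n_classes).astype(float)
        self.class_prior_ = (class_counts + self.alpha) / (
            n + self.alpha * n_classes
        )

        # discretize into integer bins per feature
        self.cutpoints_: list[list[float] | None] = [None] * p
        self._gaussian_cols: list[int] = []
        bins = np.zeros((n, p), dtype=int)
        self._n_bins: list[int] = [1] * p
        for j in range(p):
            col = X[:, j]
            if kinds[j] == BINARY:
                bins[:, j] = col.astype(int)
                self._n_bins[j] = 2
            elif self.numeric_handling == "mdl":
                cuts = mdl_discretize(col, y)
                self.cutpoints_[j] = cuts
                if cuts:
                    bins[:, j] = _bin_indices(col, cuts)
                self._n_bins[j] = len(cuts) + 1
            else:
                self._gaussian_cols.append(j)

        # Gaussian parameters for numeric columns in gaussian mode
        if self._gaussian_cols:
            g = np.asarray(self._gaussian_cols)
            self.theta_ = np.zeros((n_classes, len(g)))
            self.var_ = np.zeros((n_classes, len(g)))
            for c in range(n_classes):
                sub = X[codes == c][:, g]
                self.theta_[c] = sub.mean(axis=0)
                self.var_[c] = sub.var(axis=0)
            floor = self.var_smoothing * max(float(X.var(axis=0).max()), 1e-12)
            self.var_ = np.maximum(self.var_, max(floor, 1e-12))
        else:
            self.theta_ = self.var_ = None

        # optional one-extra-parent structure search
        self.parent_: list[int | None] = [None] * p
        if self.structure == "augmented":
            self._search_parents(bins, codes, n_classes)

        # conditional probability tables
        self.cpt_: list[np.ndarray | None] = [None] * p
        for j in range(p):
            if kinds[j] != BINARY and self.numeric_handling == "gaussian":
                continue
            nb = self._n_bins[j]
            parent = self.parent_[j]
            if parent is None:
                counts = np.zeros((n_classes, nb))
                np.add.at(counts, (codes, bins[:, j]), 1.0)
                cpt = (counts + self.alpha) / (
                    counts.sum(axis=1, keepdims=True) + self.alpha * nb
                )
            else:
                pb = self._n_bins[parent]
                counts = np.zeros((n_classes, pb, nb))
                np.add.at(counts, (codes, bins[:, parent], bins[:, j]), 1.0)
                cpt = (counts + self.alpha) / (
                    counts.sum(axis=2, keepdims=True) + self.alpha * nb
                )
            self.cpt_[j] = cpt
        return self

    def _search_parents(self, bins: np.ndarray, codes: np.ndarray, n_classes: int):
        """Greedy BIC-scored choice of at most one extra parent per feature."""
        n, p = bins.shape
        penalty = 0.5 * np.log2(max(n, 2))
        for j in range(p):
            if self._n_bins[j] < 2:
                continue
            best_score, best_parent = 0.0, None
            for q in range(p):
                if q == j or self._n_bins[q] < 2:
                    continue
                cmi = _conditional_mutual_information(
                    bins[:, j], bins[:, q], codes,
                    self._n_bins[j], self._n_bins[q], n_classes,
                )
                df = n_classes * (self._n_bins[j] - 1) * (self._n_bins[q] - 1)
                score = n * cmi - penalty * df
                if score > best_score:
                    best_score, best_parent = score, q
            self.parent_[j] = best_parent

    # -- prediction ------------------------------------------------------

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        n, p = X.shape
        if p != self.n_features_in_:
            raise SchemaError(
                f"model was fitted on {self.n_features_in_} features, got {p}"
            )
        n_classes = len(self.classes_)
        jll = np.tile(np.log(self.class_prior_), (n, 1))
        # bin indices for discrete features
        bins = np.zeros((n, p), dtype=int)
        for j in range(p):
            if self.feature_kinds_[j] == BINARY:
                # out-of-domain binary values clip to {0,1}
                bins[:, j] = np.clip(np.rint(X[:, j]), 0, 1).astype(int)
            elif self.cutpoints_[j]:
                bins[:, j] = _bin_indices(X[:, j], self.cutpoints_[j])
        # log(0) = -inf is legitimate for alpha=0 (unsmoothed) CPTs
        with np.errstate(divide="ignore"):
            for j in range(p):
                cpt = self.cpt_[j]
                if cpt is None:
                    continue
                parent = self.parent_[j]
                if parent is None:
                    jll += np.log(cpt[:, bins[:, j]]).T
                else:
                    jll += np.log(cpt[:, bins[:, parent], bins[:, j]]).T
        if self._gaussian_cols:
            g = np.asarray(self._gaussian_cols)
            for c in range(n_classes):
                diff = X[:, g] - self.theta_[c]
                jll[:, c] += (
                    -0.5 * np.log(2 * np.pi * self.var_[c])
                    - 0.5 * diff**2 / self.var_[c]
                ).sum(axis=1)
        return jll

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        jll = self._joint_log_likelihood(X)
        return np.exp(jll - logsumexp(jll, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "numeric_handling": self.numeric_handling,
            "structure": self.structure,
            "var_smoothing": self.var_smoothing,
            "classes": [str(c) for c in self.classes_],
            "class_prior": self.class_prior_.tolist(),
            "feature_kinds": list(self.feature_kinds_),
            "n_bins": list(self._n_bins),
            "cutpoints": [c if c is None else list(c) for c in self.cutpoints_],
            "parent": list(self.parent_),
            "cpt": [c.tolist() if c is not None else None for c in self.cpt_],
            "gaussian_cols": list(self._gaussian_cols),
            "theta": None if self.theta_ is None else self.theta_.tolist(),
            "var": None if self.var_ is None else self.var_.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BayesNetClassifier":
        est = cls(
            alpha=data["alpha"],
            numeric_handling=data["numeric_handling"],
            structure=data["structure"],
            var_smoothing=data["var_smoothing"],
        )
        est.classes_ = np.asarray(data["classes"], dtype=object)
        est.class_prior_ = np.asarray(data["class_prior"])
        est.feature_kinds_ = list(data["feature_kinds"])
        est.n_features_in_ = len(est.feature_kinds_)
        est._n_bins = list(data["n_bins"])
        est.cutpoints_ = [c if c is None else list(c) for c in data["cutpoints"]]
        est.parent_ = [None if p is None else int(p) for p in data["parent"]]
        est.cpt_ = [
            None if c is None else np.asarray(c, dtype=float) for c in data["cpt"]
        ]
        est._gaussian_cols = list(data["gaussian_cols"])
        est.theta_ = None if data["theta"] is None else np.asarray(data["theta"])
        est.var_ = None if data["var"] is None else np.asarray(data["var"])
        return est


def _conditional_mutual_information(
    xj: np.ndarray, xq: np.ndarray, codes: np.ndarray,
    nbj: int, nbq: int, n_classes: int,
) -> float:
    """I(Xj; Xq | C) in bits from empirical counts."""
    counts = np.zeros((n_classes, nbq, nbj))
    np.add.at(counts, (codes, xq, xj), 1.0)
    n = counts.sum()
    cmi = 0.0
    for c in range(n_classes):
        sub = counts[c]
        nc = sub.sum()
        if nc == 0:
            continue
        pj = sub.sum(axis=0) / nc
        pq = sub.sum(axis=1) / nc
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (sub / nc) / np.outer(pq, pj)
            term = np.where(sub > 0, (sub / n) * np.log2(ratio), 0.0)
        cmi += float(np.nansum(term))
    return max(cmi, 0.0)


# ---------------------------------------------------------------------------
# table-level wrapper with frozen schema
# ---------------------------------------------------------------------------


@dataclass
class PredictionResult:
    """Per-instance positive-class probability and the 0.5-threshold label."""

    ids: list[str]
    prob_positive: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.prob_positive = np.asarray(self.prob_positive, dtype=float)
        if not np.all(np.isfinite(self.prob_positive)):
            raise DomainError("probabilities must be finite")
        if np.any((self.prob_positive < 0) | (self.prob_positive > 1)):
            raise DomainError("probabilities must lie in [0, 1]")


@dataclass
class TrainedClassifier:
    """A fitted classifier plus the attribute schema it was trained on.

    ``predict`` rejects tables whose attribute names or kinds differ from
    the fit-time schema.
    """

    kind: str
    estimator: object
    attributes: list[tuple[str, str]]
    seed: int | None = None

    def _check_schema(self, table: FeatureTable) -> None:
        if list(table.attributes) != list(self.attributes):
            raise SchemaError(
                "feature table schema differs from the model's training schema"
            )

    def predict(self, table: FeatureTable) -> PredictionResult:
        self._check_schema(table)
        proba = self.estimator.predict_proba(table.values)
        classes = list(self.estimator.classes_)
        if POSITIVE_LABEL not in classes:
            raise DomainError("model classes do not include 'positive'")
        pos = proba[:, classes.index(POSITIVE_LABEL)]
        labels = [POSITIVE_LABEL if p >= 0.5 else NEGATIVE_LABEL for p in pos]
        return PredictionResult(ids=list(table.ids), prob_positive=pos, labels=labels)


def _make_estimator(kind: str, seed: int, alpha: float, **kwargs):
    if kind == "bayesnet":
        return BayesNetClassifier(alpha=alpha, **kwargs)
    if kind == "naivebayes":
        return BayesNetClassifier(alpha=alpha, numeric_handling="gaussian", **kwargs)
    if kind == "hoeffding_tree":
        # batch-trained entropy-split tree; all training here is on small
        # static tables, so no incremental (streaming) learner is needed
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "random_tree":
        return DecisionTreeClassifier(
            splitter="random", max_features="sqrt", random_state=seed
        )
    raise ConfigError(
        f"unknown classifier kind {kind!r}; expected one of {CLASSIFIER_KINDS}"
    )


def fit_baseline(
    kind: str, table: FeatureTable, seed: int = 0, alpha: float = 0.5, **kwargs
) -> TrainedClassifier:
    """Fit any of the supported classifier kinds on a labeled table."""
    labels = table.y
    if len(set(labels)) < 2:
        raise DomainError("training table contains a single class")
    est = _make_estimator(kind, seed, alpha, **kwargs)
    if isinstance(est, BayesNetClassifier) and est.feature_kinds is None:
        est.feature_kinds = table.attribute_kinds
    est.fit(table.values, labels)
    return TrainedClassifier(
        kind=kind, estimator=est, attributes=list(table.attributes), seed=seed
    )


def fit_bayesnet(
    table: FeatureTable, alpha: float = 0.5, structure: str = "naive"
) -> TrainedClassifier:
    """Fit the headline Bayesian-network classifier on a labeled table."""
    return fit_baseline("bayesnet", table, seed=0, alpha=alpha, structure=structure)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    """Write a versioned JSON model artifact.

    Bayes-family models serialize at parameter level (priors, cutpoints,
    CPTs); tree/forest baselines embed the fitted scikit-learn estimator as
    a base64 pickle field within the same envelope.
    """
    doc: dict = {
        "format_version": MODEL_FORMAT_VERSION,
        "kind": model.kind,
        "seed": model.seed,
        "attributes": [[n, k] for n, k in model.attributes],
    }
    if isinstance(model.estimator, BayesNetClassifier):
        doc["params"] = model.estimator.to_dict()
    else:
        doc["sklearn_pickle_b64"] = base64.b64encode(
            pickle.dumps(model.estimator)
        ).decode("ascii")
    with open(path, "w", newline="\n") as handle:
        json.dump(doc, handle, indent=1, sort_keys=True)
        handle.write("\n")


def load_model(path: str | Path) -> TrainedClassifier:
    with open(path) as handle:
        doc = json.load(handle)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ConfigError(
            f"unsupported model format version {doc.get('format_version')!r}"
        )
    if "params" in doc:
        est: object = BayesNetClassifier.from_dict(doc["params"])
    else:
        est = pickle.loads(base64.b64decode(doc["sklearn_pickle_b64"]))
    return TrainedClassifier(
        kind=doc["kind"],
        estimator=est,
        attributes=[(n, k) for n, k in doc["attributes"]],
        seed=doc["seed"],
    )
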