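"""Information-gain attribute ranking with supervised MDL discretization.

Attributes are scored by the reduction in Shannon class entropy (base-2)
achieved by conditioning on the attribute:

    gain(a) = H(class) - H(class | a)

Binary attributes use their two values as bins directly.  Numeric attributes
are first discretized with the Fayyad-Irani minimum-description-length
procedure: recursive binary splitting on boundary midpoints, a split being
accepted only when its information gain exceeds the MDL acceptance bound

    gain > [log2(N - 1) + log2(3^k - 2) - (k H(S) - k1 H(S1) - k2 H(S2))] / N

where k, k1, k2 are the numbers of classes present in the parent and the two
children.  An attribute whose cut list comes back empty collapses to a
single bin and scores gain 0.  An equal-frequency binning fallback is
available for unsupervised use.

This mirrors the behavior of WEKA's InfoGainAttributeEval, which the study
design this package implements relies on for attribute selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin

from .exceptions import ConfigError, DomainError
from .seqio import BINARY, FeatureTable

__all__ = [
    "class_entropy",
    "mdl_discretize",
    "equal_frequency_cutpoints",
    "info_gain",
    "select_top",
    "AttributeRanking",
    "InfoGainSelector",
    "MDLDiscretizer",
]


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector; 0 log 0 = 0."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def class_entropy(labels: Sequence) -> float:
    """Base-2 Shannon entropy of the class distribution.

    0 for pure labels, 1.0 for a balanced binary split.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DomainError("class_entropy requires at least one label")
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts)


# ---------------------------------------------------------------------------
# Fayyad-Irani MDL discretization
# ---------------------------------------------------------------------------


def _mdl_split(values: np.ndarray, codes: np.ndarray, n_classes: int) -> list[float]:
    """Recursive MDL splitting; values sorted ascending, codes are class ints."""
    n = values.size
    if n < 2:
        return []
    # candidate cuts between adjacent distinct values
    change = np.nonzero(np.diff(values) > 0)[0]  # cut after index i
    if change.size == 0:
        return []
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), codes] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    h_s = _entropy_from_counts(total)
    best_gain, best_i = -1.0, -1
    for i in change:
        left, right = cum[i], total - cum[i]
        n1, n2 = left.sum(), right.sum()
        cond = (n1 * _entropy_from_counts(left) + n2 * _entropy_from_counts(right)) / n
        gain = h_s - cond
        if gain > best_gain:
            best_gain, best_i = gain, int(i)
    left, right = cum[best_i], total - cum[best_i]
    k = int((total > 0).sum())
    k1 = int((left > 0).sum())
    k2 = int((right > 0).sum())
    delta = np.log2(3.0**k - 2.0) - (
        k * h_s
        - k1 * _entropy_from_counts(left)
        - k2 * _entropy_from_counts(right)
    )
    threshold = (np.log2(n - 1.0) + delta) / n
    if best_gain <= threshold:
        return []
    cut = float((values[best_i] + values[best_i + 1]) / 2.0)
    lo = _mdl_split(values[: best_i + 1], codes[: best_i + 1], n_classes)
    hi = _mdl_split(values[best_i + 1 :], codes[best_i + 1 :], n_classes)
    return lo + [cut] + hi


def mdl_discretize(values: Sequence[float], labels: Sequence) -> list[float]:
    """Fayyad-Irani supervised discretization; returns sorted cutpoints.

    An empty list means the attribute collapses to a single bin (and will
    score an information gain of 0).  Degenerate inputs (constant values,
    pure labels, fewer than 2 instances) yield an empty cut list rather than
    an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise DomainError("values and labels must have the same length")
    if values.size == 0:
        return []
    order = np.argsort(values, kind="stable")
    classes, codes = np.unique(labels, return_inverse=True)
    return _mdl_split(values[order], codes[order], len(classes))


def equal_frequency_cutpoints(values: Sequence[float], bins: int = 10) -> list[float]:
    """Unsupervised fallback: cutpoints at equal-frequency quantiles."""
    if bins < 2:
        raise ConfigError("equal-frequency binning requires bins >= 2")
    values = np.asarray(values, dtype=float)
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    cuts = sorted(set(float(q) for q in qs))
    # drop cuts outside the open value range (constant columns -> no cuts)
    return [c for c in cuts if values.min() < c < values.max()]


def _bin_indices(column: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    """Bin index per value; values beyond the range fall into the end bins."""
    return np.searchsorted(np.asarray(cutpoints, dtype=float), column, side="right")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


@dataclass
class AttributeRanking:
    """Information-gain ranking of a labeled feature table's attributes.

    ``entries`` is sorted by gain descending with ties broken by original
    attribute order (stable), so reports are deterministic.
    """

    entries: list[tuple[str, float]]
    class_entropy: float
    discretization_cutpoints: dict[str, list[float]] = field(default_factory=dict)

    def gains(self) -> dict[str, float]:
        return dict(self.entries)

    def to_tsv(self) -> str:
        lines = ["attribute\tinfo_gain\tcutpoints"]
        for name, gain in self.entries:
            cuts = self.discretization_cutpoints.get(name, [])
            lines.append(f"{name}\t{gain:.10g}\t{','.join(f'{c:.10g}' for c in cuts)}")
        return "\n".join(lines) + "\n"


def _attribute_gain(
    column: np.ndarray,
    kind: str,
    codes: np.ndarray,
    n_classes: int,
    h_class: float,
    labels: np.ndarray,
    discretization: str,
    bins: int,
) -> tuple[float, list[float]]:
    if kind == BINARY:
        bin_idx = column.astype(int)
        cuts: list[float] = []
    else:
        if discretization == "mdl":
            cuts = mdl_discretize(column, labels)
        elif discretization == "equal_frequency":
            cuts = equal_frequency_cutpoints(column, bins)
        else:
            raise ConfigError(f"unknown discretization {discretization!r}")
        if not cuts:
            return 0.0, []
        bin_idx = _bin_indices(column, cuts)
    n = column.size
    n_bins = int(bin_idx.max()) + 1
    cond = 0.0
    for b in range(n_bins):
        mask = bin_idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        counts = np.bincount(codes[mask], minlength=n_classes)
        cond += (nb / n) * _entropy_from_counts(counts)
    return max(0.0, h_class - cond), cuts


def info_gain(
    table: FeatureTable,
    discretization: str = "mdl",
    bins: int = 10,
) -> AttributeRanking:
    """Rank every attribute of a labeled table by information gain.

    Numeric attributes are discretized (``mdl`` by default,
    ``equal_frequency`` as fallback) before the gain is computed from the
    bin x class contingency table.
    """
    labels = table.y
    classes, codes = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise DomainError("information gain requires at least two classes present")
    h_class = class_entropy(labels)
    scored: list[tuple[str, float]] = []
    cutpoints: dict[str, list[float]] = {}
    for j, (name, kind) in enumerate(table.attributes):
        gain, cuts = _attribute_gain(
            table.values[:, j], kind, codes, len(classes), h_class, labels,
            discretization, bins,
        )
        scored.append((name, gain))
        if cuts:
            cutpoints[name] = cuts
    order = sorted(range(len(scored)), key=lambda j: -scored[j][1])  # stable
    return AttributeRanking(
        entries=[scored[j] for j in order],
        class_entropy=h_class,
        discretization_cutpoints=cutpoints,
    )


def select_top(
    ranking: AttributeRanking,
    k: int | None = None,
    min_gain: float | None = None,
) -> list[str]:
    """Pick attributes off the top of a ranking.

    Exactly one of ``k`` (keep the k best, ties resolved by the ranking's
    stable order) or ``min_gain`` (keep attributes with gain strictly above
    the threshold; ``min_gain=0`` keeps strictly positive gains) must be
    given.  ``k`` larger than the attribute count returns everything, with a
    warning.
    """
    if (k is None) == (min_gain is None):
        raise ConfigError("select_top requires exactly one of k or min_gain")
    if k is not None:
        if k < 1:
            raise ConfigError("k must be >= 1")
        if k > len(ranking.entries):
            warnings.warn(
                f"requested k={k} attributes but only {len(ranking.entries)} exist; "
                "returning all",
                stacklevel=2,
            )
        return [name for name, _ in ranking.entries[:k]]
    if min_gain < 0:
        raise ConfigError("min_gain must be >= 0")
    return [name for name, gain in ranking.entries if gain > min_gain]


# ---------------------------------------------------------------------------
# sklearn-compatible estimators
# ---------------------------------------------------------------------------


def _infer_kinds(X: np.ndarray) -> list[str]:
    """Binary iff every value in the column is 0 or 1."""
    return [
        BINARY if X.shape[0] and np.all(np.isin(X[:, j], (0.0, 1.0))) else "numeric"
        for j in range(X.shape[1])
    ]


class MDLDiscretizer(TransformerMixin, BaseEstimator):
    """Supervised Fayyad-Irani discretizer for numeric feature matrices.

    ``fit(X, y)`` learns per-column cutpoints; ``transform`` maps values to
    integer bin indices (out-of-range values fall into the end bins).
    Columns whose cut list is empty collapse to a single bin of zeros.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.cutpoints_ = [mdl_discretize(X[:, j], y) for j in range(X.shape[1])]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise DomainError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        out = np.zeros(X.shape, dtype=int)
        for j, cuts in enumerate(self.cutpoints_):
            if cuts:
                out[:, j] = _bin_indices(X[:, j], cuts)
        return out


class InfoGainSelector(SelectorMixin, BaseEstimator):
    """Attribute selection by information gain, sklearn-pipeline compatible.

    Parameters
    ----------
    k : keep the k highest-gain features (ties by original column order).
    min_gain : alternatively, keep features with gain strictly above this.
    discretization : ``"mdl"`` (supervised, default) or
        ``"equal_frequency"`` with ``bins`` bins.
    """

    def __init__(
        self,
        k: int | None = None,
        min_gain: float | None = None,
        discretization: str = "mdl",
        bins: int = 10,
    ):
        self.k = k
        self.min_gain = min_gain
        self.discretization = discretization
        self.bins = bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise DomainError("X must be 2-D with one label per row")
        kinds = _infer_kinds(X)
        names = [f"x{j}" for j in range(X.shape[1])]
        uniq = set(np.unique(y).tolist())
        if uniq <= {"positive", "negative"}:
            labels = y.astype(object)
        else:  # arbitrary binary labels: highest value plays "positive"
            top = np.unique(y)[-1]
            labels = np.where(y == top, "positive", "negative").astype(object)
        table = FeatureTable(
            ids=[f"i{r}" for r in range(X.shape[0])],
            attributes=list(zip(names, kinds)),
            values=X,
            labels=labels,
        )
        ranking = info_gain(table, self.discretization, self.bins)
        self.ranking_ = ranking
        gains = ranking.gains()
        self.gains_ = np.asarray([gains[n] for n in names])
        selected = set(select_top(ranking, k=self.k, min_gain=self.min_gain))
        self.support_ = np.asarray([n in selected for n in names])
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_
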