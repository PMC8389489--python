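"""Supervised best-k feature refinement by plug-in mutual information.

Once labels are available, each surviving feature is scored by the
mutual information (in bits) between its equal-frequency-discretized
values and the binarized class label; zero-MI features are dropped and
the top-k kept.  Works as a scikit-learn selector so it can sit inside
a pipeline whose folds guarantee it only ever sees training rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = ["MIResult", "mutual_information", "discrete_mutual_information",
           "select_best_k", "MutualInfoSelector", "binarize_ratings"]


def binarize_ratings(ratings: np.ndarray, threshold: float = 5.0) -> np.ndarray:
    """High/low classes from 1-9 self-report ratings (midpoint split)."""
    return (np.asarray(ratings, dtype=float) > threshold).astype(int)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.digitize(x, edges)


def discrete_mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (bits) between two already-discrete variables."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("inputs must have the same length")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((len(ua), len(ub)))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 8) -> float:
    """MI (bits) between a continuous feature and a binary label.

    ``x`` is discretized into ``bins`` equal-frequency bins; the result
    is the plug-in estimate, clipped at zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    return discrete_mutual_information(_equal_frequency_bins(x, bins), y)


@dataclass
class MIResult:
    """Per-feature MI, the kept top-k, and the dropped zero-MI features."""

    mi: dict[str, float]
    kept: tuple[str, ...]
    dropped_zero: tuple[str, ...]
    binning: int
    kept_idx: tuple[int, ...] = field(default=())


def select_best_k(X: np.ndarray, y: np.ndarray, k: int, bins: int = 8,
                  feature_names: tuple[str, ...] | None = None,
                  prior_order: tuple[str, ...] | None = None) -> MIResult:
    """Keep the k features most informative about y.

    Strictly zero-MI features are eliminated outright.  Ties are broken
    by ``prior_order`` (the upstream unsupervised ranking) when given,
    else by feature name.  Asking for more features than survive keeps
    them all with a warning.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length mismatch")
    mi = {name: mutual_information(X[:, i], y, bins=bins)
          for i, name in enumerate(feature_names)}
    nonzero = [n for n in feature_names if mi[n] > 0.0]
    dropped = tuple(n for n in feature_names if mi[n] == 0.0)
    if k > len(nonzero):
        import warnings
        warnings.warn(f"k={k} exceeds the {len(nonzero)} surviving features; keeping all")
        k = len(nonzero)
    if prior_order is not None:
        prior_rank = {n: r for r, n in enumerate(prior_order)}
        key = lambda n: (-mi[n], prior_rank.get(n, len(prior_order)), n)
    else:
        key = lambda n: (-mi[n], n)
    kept = tuple(sorted(nonzero, key=key)[:k])
    name_to_idx = {n: i for i, n in enumerate(feature_names)}
    return MIResult(mi=mi, kept=kept, dropped_zero=dropped, binning=bins,
                    kept_idx=tuple(name_to_idx[n] for n in kept))


class MutualInfoSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector keeping the top-k features by plug-in MI.

    Parameters
    ----------
    k : int
        Number of features to keep (capped at the nonzero-MI count).
    bins : int
        Equal-frequency bins for discretizing each feature.

    Fitted attributes: ``mi_`` (per-column MI in bits), ``result_``
    (:class:`MIResult`), ``support_mask_``.
    """

    def __init__(self, k: int = 10, bins: int = 8):
        self.k = k
        self.bins = bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        names = tuple(f"f{i}" for i in range(X.shape[1]))
        self.result_ = select_best_k(X, y, k=self.k, bins=self.bins,
                                     feature_names=names)
        self.mi_ = np.array([self.result_.mi[n] for n in names])
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[list(self.result_.kept_idx)] = True
        self.support_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_mask_
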