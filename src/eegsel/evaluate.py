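"""Subject-independent nested cross-validation and the channel-fraction sweep.

Each stimulus is treated as one classification problem whose data points
are subjects: the outer loop leaves one subject out, the inner loop
(stratified, grouped by subject) performs MI-based feature selection and
an SVM grid search over C in {.025, .5, 1, 10, 100} with linear and RBF
kernels (RBF scale in {0.001, 2, 10, 50, 100}), and the winning
configuration is refit on all training subjects and scored on the held
out subject's epochs.  Channel and feature rankings entering a fold are
aggregated over the *training* subjects only, so the test subject's data
never influences any selection step (the report carries a fold audit
trail asserting this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, balanced_accuracy_score
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .channels import select_top_fraction
from .features import FeatureTensor
from .laplacian import aggregate_rankings
from .mi import select_best_k

__all__ = [
    "DEFAULT_GRID", "DEFAULT_FRACTIONS", "grid_configs", "f1_score",
    "EvalReport", "nested_cv", "fraction_sweep_report",
]

DEFAULT_GRID = {
    "C": (0.025, 0.5, 1, 10, 100),
    "kernels": ("linear", "rbf"),
    "rbf_scale": (0.001, 2, 10, 50, 100),
}
DEFAULT_FRACTIONS = tuple(round(0.1 * i, 1) for i in range(1, 11))


def grid_configs(grid: dict | None = None) -> list[dict]:
    """Enumerate the SVM hyperparameter grid (linear first)."""
    grid = dict(DEFAULT_GRID if grid is None else grid)
    configs = []
    for kernel in grid["kernels"]:
        for C in grid["C"]:
            if kernel == "linear":
                configs.append(dict(kernel="linear", C=C, gamma=None))
            else:
                for g in grid["rbf_scale"]:
                    configs.append(dict(kernel=kernel, C=C, gamma=g))
    return configs


def f1_score(y_true, y_pred) -> float:
    """F1 of the positive ("high") class; 0 when nothing positive is predicted."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(_sk_f1(y_true, y_pred, pos_label=1, zero_division=0))


@dataclass
class EvalReport:
    """Per-(stimulus, fold, target, fraction) records plus an audit trail.

    Each row carries the held-out subject's epoch-level confusion counts
    (tp/fp/fn/tn).  Because every fold's epochs share one true label, a
    single fold cannot carry a meaningful F1 on its own — the per-trial
    F1 pools the predictions of all subjects for that stimulus.
    """

    rows: pd.DataFrame
    audit: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def stimulus_f1(self, target: str = "valence",
                    fraction: float | None = None) -> pd.DataFrame:
        """Pooled epoch-level F1 per stimulus (subjects are the data points)."""
        df = self.rows[self.rows.target == target]
        if fraction is not None:
            df = df[df.fraction == fraction]
        out = []
        for (stim, frac), grp in df.groupby(["stimulus", "fraction"]):
            tp, fp, fn = grp.tp.sum(), grp.fp.sum(), grp.fn.sum()
            denom = tp + 0.5 * (fp + fn)
            f1 = float(tp / denom) if denom > 0 else 0.0
            acc = float((grp.tp.sum() + grp.tn.sum())
                        / (grp[["tp", "fp", "fn", "tn"]].to_numpy().sum()))
            out.append(dict(stimulus=stim, fraction=frac, f1=f1, accuracy=acc))
        return pd.DataFrame(out)

    def mean_f1(self, target: str = "valence",
                fraction: float | None = None) -> float:
        """Mean over stimuli of the pooled per-stimulus F1."""
        per_stim = self.stimulus_f1(target, fraction)
        return float(per_stim.f1.mean()) if len(per_stim) else 0.0

    def mean_accuracy(self, target: str = "valence",
                      fraction: float | None = None) -> float:
        per_stim = self.stimulus_f1(target, fraction)
        return float(per_stim.accuracy.mean()) if len(per_stim) else 0.0

    def subject_level_f1(self, target: str = "valence",
                         fraction: float | None = None) -> float:
        """F1 of the per-subject majority-vote predictions across folds."""
        df = self.rows[self.rows.target == target]
        if fraction is not None:
            df = df[df.fraction == fraction]
        return f1_score(df.subject_true.to_numpy(), df.subject_pred.to_numpy())

    def summary(self) -> pd.DataFrame:
        rows = []
        for target in self.rows.target.unique():
            per_stim = self.stimulus_f1(target)
            for frac, grp in per_stim.groupby("fraction"):
                rows.append(dict(target=target, fraction=frac,
                                 mean=float(grp.f1.mean()),
                                 std=float(grp.f1.std()),
                                 median=float(grp.f1.median())))
        return pd.DataFrame(rows)


def _flatten(ft: FeatureTensor, channels: tuple[str, ...],
             features: tuple[str, ...]) -> np.ndarray:
    ch_idx = [ft.channel_names.index(c) for c in channels]
    f_idx = [ft.feature_names.index(f) for f in features]
    sub = ft.values[np.ix_(range(ft.n_epochs), ch_idx, f_idx)]
    return sub.reshape(ft.n_epochs, -1)


def _column_names(channels, features) -> tuple[str, ...]:
    return tuple(f"{c}:{f}" for c in channels for f in features)


def _make_svc(cfg: dict) -> SVC:
    if cfg["kernel"] == "linear":
        return SVC(kernel="linear", C=cfg["C"], class_weight="balanced")
    # the grid lists RBF kernel *scales* (length-scales sigma); sklearn's
    # gamma is 1/sigma^2
    gamma = 1.0 / cfg["gamma"] ** 2
    return SVC(kernel="rbf", C=cfg["C"], gamma=gamma, class_weight="balanced")


def _fit_score(cfg, X_tr, y_tr, X_va, y_va) -> float:
    # selection metric: balanced accuracy — a degenerate one-class
    # predictor scores 0.5 even when the tiny grouped validation fold
    # happens to contain a single class, which positive-class F1 rewards
    clf = _make_svc(cfg)
    clf.fit(X_tr, y_tr)
    return float(balanced_accuracy_score(y_va, clf.predict(X_va)))


def _select_columns(X, y, k_features, bins, col_names, prior_order) -> list[int]:
    """MI-based column choice; tiny folds fall back to the upstream order."""
    if len(y) < 10:
        return list(range(min(k_features, X.shape[1])))
    res = select_best_k(X, y, k=k_features, bins=bins,
                        feature_names=col_names, prior_order=prior_order)
    return list(res.kept_idx) or list(range(X.shape[1]))


def _inner_select_and_search(X, y, groups, configs, k_features, bins,
                             prior_order, col_names, inner_folds):
    """Grid search with MI selection refit inside every inner fold."""
    classes, counts = np.unique(y, return_counts=True)
    uniq_groups_per_class = min(
        len(np.unique(groups[y == c])) for c in classes
    )
    n_splits = max(2, min(inner_folds, uniq_groups_per_class))
    splitter = StratifiedGroupKFold(n_splits=n_splits)
    scores = np.zeros(len(configs))
    n_folds = 0
    for tr, va in splitter.split(X, y, groups):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            continue
        idx = _select_columns(X[tr], y[tr], k_features, bins, col_names,
                              prior_order)
        if not idx:
            continue
        scaler = StandardScaler().fit(X[tr][:, idx])
        X_tr = scaler.transform(X[tr][:, idx])
        X_va = scaler.transform(X[va][:, idx])
        for ci, cfg in enumerate(configs):
            scores[ci] += _fit_score(cfg, X_tr, y[tr], X_va, y[va])
        n_folds += 1
    if n_folds == 0:
        return configs[0]
    return configs[int(np.argmax(scores / n_folds))]


def nested_cv(features: dict[str, dict[str, FeatureTensor]],
              labels: pd.DataFrame,
              channel_rankings: dict[str, tuple[str, ...]],
              feature_rankings: dict[str, tuple[str, ...]] | None = None,
              grid: dict | None = None,
              fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
              targets: tuple[str, ...] = ("valence", "arousal"),
              feature_top_fraction: float = 1.0 / 3.0,
              k_features: int = 32,
              bins: int = 8,
              inner_folds: int = 3) -> EvalReport:
    """Leave-one-subject-out nested CV per stimulus over channel fractions.

    Parameters
    ----------
    features
        ``features[subject_id][trial_id]`` -> per-trial FeatureTensor.
    labels
        Long table with ``subject_id, trial_id, valence_class,
        arousal_class`` columns.
    channel_rankings, feature_rankings
        Per-subject unsupervised orders (best first); within each fold
        they are mean-rank aggregated over training subjects only.
    """
    subjects = sorted(features)
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for leave-one-subject-out")
    configs = grid_configs(grid)
    stimuli = sorted({t for s in subjects for t in features[s]})
    any_ft = next(iter(features[subjects[0]].values()))
    all_channels = any_ft.channel_names
    all_features = any_ft.feature_names

    label_of = {(r.subject_id, r.trial_id): {t: int(getattr(r, f"{t}_class"))
                                             for t in targets}
                for r in labels.itertuples()}
    rows, audit = [], []
    for target in targets:
        for stim in stimuli:
            stim_subjects = [s for s in subjects if stim in features[s]]
            y_subj = {s: label_of[(s, stim)][target] for s in stim_subjects}
            if len(set(y_subj.values())) < 2:
                warnings.warn(f"stimulus {stim}: single-class {target} labels; skipped")
                continue
            for test_subject in stim_subjects:
                train = [s for s in stim_subjects if s != test_subject]
                if len(set(y_subj[s] for s in train)) < 2:
                    warnings.warn(
                        f"stimulus {stim}, fold {test_subject}: single-class training "
                        f"{target} labels; fold skipped")
                    continue
                ch_order = aggregate_rankings([channel_rankings[s] for s in train])
                if feature_rankings is not None:
                    f_order = aggregate_rankings([feature_rankings[s] for s in train])
                    n_keep = int(np.ceil(feature_top_fraction * len(f_order)))
                    feats = tuple(f_order[:n_keep])
                else:
                    feats = all_features
                audit.append(dict(target=target, stimulus=stim,
                                  test_subject=test_subject,
                                  train_subjects=tuple(train)))
                for fraction in fractions:
                    channels = select_top_fraction(ch_order, fraction)
                    col_names = _column_names(channels, feats)
                    X_by_subj = {s: _flatten(features[s][stim], channels, feats)
                                 for s in stim_subjects}
                    X_tr = np.vstack([X_by_subj[s] for s in train])
                    y_tr = np.concatenate([
                        np.full(len(X_by_subj[s]), y_subj[s]) for s in train])
                    g_tr = np.concatenate([
                        np.full(len(X_by_subj[s]), i) for i, s in enumerate(train)])
                    prior = _column_names(channels, feats)  # upstream order
                    best = _inner_select_and_search(
                        X_tr, y_tr, g_tr, configs, k_features, bins,
                        prior, col_names, inner_folds)
                    idx = _select_columns(X_tr, y_tr, k_features, bins,
                                          col_names, prior)
                    scaler = StandardScaler().fit(X_tr[:, idx])
                    clf = _make_svc(best)
                    clf.fit(scaler.transform(X_tr[:, idx]), y_tr)
                    X_te = X_by_subj[test_subject][:, idx]
                    y_te = np.full(len(X_te), y_subj[test_subject])
                    pred = clf.predict(scaler.transform(X_te))
                    maj = int(np.round(pred.mean() + 1e-9)) if len(pred) else 0
                    tp = int(np.sum((y_te == 1) & (pred == 1)))
                    fp = int(np.sum((y_te == 0) & (pred == 1)))
                    fn = int(np.sum((y_te == 1) & (pred == 0)))
                    tn = int(np.sum((y_te == 0) & (pred == 0)))
                    rows.append(dict(
                        target=target, stimulus=stim, test_subject=test_subject,
                        fraction=fraction, f1=f1_score(y_te, pred),
                        accuracy=float(accuracy_score(y_te, pred)),
                        tp=tp, fp=fp, fn=fn, tn=tn,
                        subject_true=y_subj[test_subject], subject_pred=maj,
                        kernel=best["kernel"], C=best["C"], gamma=best["gamma"],
                        n_channels=len(channels), n_features=len(idx),
                    ))
    report = EvalReport(
        rows=pd.DataFrame(rows), audit=audit,
        config=dict(grid=grid or DEFAULT_GRID, fractions=fractions,
                    targets=targets, k_features=k_features, bins=bins,
                    feature_top_fraction=feature_top_fraction,
                    inner_folds=inner_folds),
    )
    return report


def fraction_sweep_report(report: EvalReport) -> pd.DataFrame:
    """Box-plot statistics of per-stimulus pooled F1 across channel fractions."""
    rows = []
    for target in report.rows.target.unique():
        per_stim = report.stimulus_f1(target)
        for fraction, grp in per_stim.groupby("fraction"):
            rows.append(dict(
                target=target, fraction=fraction,
                median=float(grp.f1.median()),
                q1=float(grp.f1.quantile(0.25)),
                q3=float(grp.f1.quantile(0.75)),
                mean=float(grp.f1.mean()),
                n_stimuli=int(len(grp)),
            ))
    return pd.DataFrame(rows)
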