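"""End-to-end orchestration: recordings -> features -> rankings -> report."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .channels import ChannelSelector
from .evaluate import EvalReport, nested_cv
from .features import FeatureTensor, extract
from .laplacian import LaplacianScoreRanker
from .montage import load_montage
from .preprocess import Preprocessor
from .recording import Recording

__all__ = ["Study", "build_study", "evaluate_study"]


@dataclass
class Study:
    """Per-subject feature tensors plus the unsupervised rankings."""

    features: dict[str, dict[str, FeatureTensor]]
    labels: pd.DataFrame
    channel_rankings: dict[str, tuple[str, ...]]
    feature_rankings: dict[str, tuple[str, ...]]
    montage_name: str
    params: dict = field(default_factory=dict)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(self.features))


def build_study(recordings: list[Recording], labels: pd.DataFrame,
                montage_name: str = "standard_1020_32", w: float = 2.0,
                classify_w: float | None = None,
                notch_hz: float = 50.0, band: tuple[float, float] = (0.5, 40.0),
                fs_out: float = 128.0, ica: bool = True,
                laplacian_k: int = 5, kappa_max: int = 2, damping: float = 0.9,
                alpha: float = 0.0, random_state: int = 0) -> Study:
    """Preprocess every trial, extract features, fit both rankers per subject.

    ``w`` is the epoch width used for the unsupervised rankings; small
    windows give the co-activation consensus the most epochs to average
    over.  ``classify_w`` (default: same as ``w``) is the width of the
    epochs whose features feed the classifier — larger windows smooth
    spontaneous band-power fluctuation and stabilise per-epoch class
    evidence.  Both come from the studied {2, 5, 10} s set.
    """
    from .preprocess import epoch as _epoch
    if classify_w is None:
        classify_w = w
    pre = Preprocessor(notch_hz=notch_hz, band=band, fs_out=fs_out, w=w,
                       ica=ica, random_state=random_state)
    montage = load_montage(montage_name)
    features: dict[str, dict[str, FeatureTensor]] = {}
    ranking_features: dict[str, dict[str, FeatureTensor]] = {}
    for rec in recordings:
        continuous = pre.preprocess_continuous(rec)
        ft_rank = extract(_epoch(continuous, w))
        ranking_features.setdefault(rec.subject_id, {})[rec.trial_id] = ft_rank
        if classify_w == w:
            ft_cls = ft_rank
        else:
            ft_cls = extract(_epoch(continuous, classify_w))
        features.setdefault(rec.subject_id, {})[rec.trial_id] = ft_cls

    channel_rankings, feature_rankings = {}, {}
    for sid, trials in ranking_features.items():
        tensors = [trials[t] for t in sorted(trials)]
        lap = LaplacianScoreRanker(k=laplacian_k).fit(tensors)
        feature_rankings[sid] = lap.ranking_.order
        sel = ChannelSelector(montage, kappa_max=kappa_max, damping=damping,
                              alpha=alpha).fit(tensors)
        channel_rankings[sid] = sel.ranking_
    return Study(
        features=features, labels=labels,
        channel_rankings=channel_rankings, feature_rankings=feature_rankings,
        montage_name=montage_name,
        params=dict(w=w, classify_w=classify_w, notch_hz=notch_hz, band=band,
                    fs_out=fs_out, ica=ica, laplacian_k=laplacian_k,
                    kappa_max=kappa_max, damping=damping, alpha=alpha,
                    random_state=random_state),
    )


def evaluate_study(study: Study, **cv_kwargs) -> EvalReport:
    """Nested LOSO cross-validation over the study's feature tensors."""
    report = nested_cv(study.features, study.labels,
                       channel_rankings=study.channel_rankings,
                       feature_rankings=study.feature_rankings, **cv_kwargs)
    report.config["study_params"] = study.params
    return report
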