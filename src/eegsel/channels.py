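"""Subject-specific channel selection from inter-channel co-activation.

For every epoch, channels are compared by the Pearson correlation of
their feature vectors, clustered with affinity propagation (exemplar
election by responsibility/availability message passing), and linked in
a co-activation graph whose edges are *down-weighted* for spatially
close electrode pairs (near channels read overlapping neural sources,
so their correlation is less informative than correlation between far
channels).  Epochs whose cluster structure is inconsistent with the
cross-epoch consensus are discarded, and channels are ranked by a blend
of how often they are elected exemplar and their functional (spatially
discounted) connection strength in the retained epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .features import FeatureTensor
from .montage import Montage

__all__ = [
    "DeltaMatrix", "EpochClustering", "ChannelRanking",
    "neighboring_matrix", "channel_similarity", "affinity_propagation",
    "build_coactivation_graph", "rank_channels", "aggregate_trial_rankings",
    "select_top_fraction", "spatial_factor", "ChannelSelector",
]


@dataclass
class DeltaMatrix:
    """Topological channel distances: shortest-path hop counts <= kappa_max.

    Entries are the hop count kappa when 0 < kappa <= kappa_max, and 0
    otherwise (self-pairs and pairs farther than the cap).
    """

    delta: np.ndarray
    kappa_max: int
    channel_names: tuple[str, ...]


@dataclass
class EpochClustering:
    """Affinity-propagation outcome for one epoch."""

    S: np.ndarray
    exemplars: tuple[int, ...]
    labels: np.ndarray  # exemplar index each channel is assigned to
    L: np.ndarray  # co-membership indicator, zero diagonal
    converged: bool
    iterations: int


@dataclass
class ChannelRanking:
    """Descending-score channel order with its ingredients."""

    scores: dict[str, float]
    order: tuple[str, ...]
    retained_epochs: tuple[int, ...]
    exemplar_frequency: dict[str, float] = field(default_factory=dict)
    functional_strength: dict[str, float] = field(default_factory=dict)


def neighboring_matrix(m: Montage, kappa_max: int = 2) -> DeltaMatrix:
    """Capped shortest-path hop distances on the montage adjacency graph."""
    if kappa_max < 1:
        raise ValueError("kappa_max must be >= 1")
    if not nx.is_connected(m.graph):
        comps = sorted(nx.connected_components(m.graph), key=len, reverse=True)
        isolated = sorted(n for comp in comps[1:] for n in comp)
        raise ValueError(f"montage graph is disconnected; isolated channels: {isolated}")
    n = len(m.names)
    delta = np.zeros((n, n), dtype=int)
    hops = dict(nx.all_pairs_shortest_path_length(m.graph))
    for i, p in enumerate(m.names):
        for j, q in enumerate(m.names):
            if p == q:
                continue
            kappa = hops[p][q]
            delta[i, j] = kappa if kappa <= kappa_max else 0
    return DeltaMatrix(delta=delta, kappa_max=kappa_max, channel_names=m.names)


def channel_similarity(X_t: np.ndarray, standardize: str = "channels") -> np.ndarray:
    """Pearson correlation between channel feature vectors for one epoch.

    With ``standardize="channels"`` feature columns are z-scored across
    channels first so that large-magnitude features do not dominate;
    ``"none"`` correlates the rows as given (used when the caller has
    already standardized the feature tensor, e.g. across epochs).  A
    channel whose (scaled) feature vector has zero variance gets zero
    similarity to everything.
    """
    X_t = np.asarray(X_t, dtype=float)
    if X_t.ndim != 2 or X_t.shape[1] < 2:
        raise ValueError("need a (channels x features) matrix with >= 2 features")
    if standardize == "channels":
        mu, sd = X_t.mean(axis=0), X_t.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X_t - mu) / sd
    elif standardize == "none":
        Z = X_t
    else:
        raise ValueError(f"unknown standardize mode {standardize!r}")
    rows_c = Z - Z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows_c, axis=1)
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    S = (rows_c / safe[:, None]) @ (rows_c / safe[:, None]).T
    S[~valid, :] = 0.0
    S[:, ~valid] = 0.0
    np.clip(S, -1.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    return S


def affinity_propagation(S: np.ndarray, damping: float = 0.9,
                         preference: float | None = None,
                         max_iter: int = 500,
                         convergence_iter: int = 25) -> EpochClustering:
    """Exemplar election by damped responsibility/availability passing.

    ``preference`` (the similarity of each point to itself) defaults to
    the median off-diagonal similarity.  Exemplars are the points k with
    ``alpha_kk + rho_kk > 0``; every point is assigned to the exemplar
    maximizing ``alpha_ik + rho_ik``.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if not (0.5 <= damping < 1.0):
        raise ValueError("damping must be in [0.5, 1)")
    work = S.copy()
    if preference is None:
        off = work[~np.eye(n, dtype=bool)]
        preference = float(np.median(off)) if off.size else 0.0
    np.fill_diagonal(work, preference)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    rows = np.arange(n)
    stable = 0
    E_prev = np.zeros(n, dtype=bool)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities: rho_ik = S_ik - max_{k' != k}(S_ik' + alpha_ik')
        AS = A + work
        top_idx = np.argmax(AS, axis=1)
        top_val = AS[rows, top_idx]
        AS[rows, top_idx] = -np.inf
        second_val = AS.max(axis=1)
        Rnew = work - top_val[:, None]
        Rnew[rows, top_idx] = work[rows, top_idx] - second_val
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, np.diag(R))
        col_sum = Rp.sum(axis=0)
        Anew = col_sum[None, :] - Rp
        diag_A = np.diag(Anew).copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, diag_A)
        A = damping * A + (1.0 - damping) * Anew

        E = (np.diag(A) + np.diag(R)) > 0
        if np.array_equal(E, E_prev) and E.any():
            stable += 1
            if stable >= convergence_iter:
                converged = True
                break
        else:
            stable = 0
        E_prev = E

    crit = np.diag(A) + np.diag(R)
    exemplars = np.flatnonzero(crit > 0)
    if len(exemplars) == 0:
        exemplars = np.array([int(np.argmax(crit))])
    evidence = (A + R)[:, exemplars]
    labels = exemplars[np.argmax(evidence, axis=1)]
    labels[exemplars] = exemplars
    L = (labels[:, None] == labels[None, :]).astype(int)
    np.fill_diagonal(L, 0)
    return EpochClustering(S=S, exemplars=tuple(int(e) for e in exemplars),
                           labels=labels, L=L, converged=converged, iterations=it)


def spatial_factor(delta: np.ndarray, kappa_max: int) -> np.ndarray:
    """Edge discount: delta/(kappa_max+1) for capped near pairs, 1 otherwise."""
    near = (delta > 0) & (delta <= kappa_max)
    return np.where(near, delta / (kappa_max + 1.0), 1.0)


def build_coactivation_graph(S: np.ndarray, L: np.ndarray,
                             delta: DeltaMatrix) -> np.ndarray:
    """Weighted co-activation graph for one epoch.

    ``w_ij = L_ij * max(S_ij, 0) * spatial_factor(delta_ij)`` — only
    co-clustered, positively correlated pairs are linked, and spatially
    close pairs are discounted.
    """
    S = np.asarray(S, dtype=float)
    L = np.asarray(L)
    if S.shape != L.shape or S.shape != delta.delta.shape:
        raise ValueError("S, L and delta must share one shape")
    W = L * np.maximum(S, 0.0) * spatial_factor(delta.delta, delta.kappa_max)
    np.fill_diagonal(W, 0.0)
    return W


def _offdiag(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    return M[~np.eye(n, dtype=bool)]


def _consistency(l_vec: np.ndarray, m_vec: np.ndarray) -> float:
    sl, sm = l_vec.std(), m_vec.std()
    if sl == 0 or sm == 0:
        return 1.0 if np.allclose(l_vec, m_vec) else 0.0
    return float(np.corrcoef(l_vec, m_vec)[0, 1])


def rank_channels(clusterings: list[EpochClustering], graphs: list[np.ndarray],
                  channel_names: tuple[str, ...],
                  alpha: float = 0.0,
                  delta: DeltaMatrix | None = None,
                  epoch_filter: str = "none") -> ChannelRanking:
    """Consensus channel scoring over the epochs of a session.

    The consensus co-membership M is the mean of the per-epoch L
    matrices.  With ``delta`` given, channel i's *persistent
    co-activation strength* is

        sum_j ( M_ij * max(mean_t S_t_ij, 0) * spatial_factor(delta_ij) )^2

    — a pair contributes only insofar as it co-clusters *consistently*
    and stays positively correlated on average, with spatially close
    pairs discounted; squaring emphasises a channel's strongest
    persistent partnerships over accumulations of weak transient ones.
    Without ``delta`` the strength falls back to the mean weighted
    degree in the per-epoch co-activation graphs.  Strengths are
    rescaled to [0, 1] and blended with the channel's exemplar
    frequency as ``alpha * freq + (1 - alpha) * strength`` (the default
    ``alpha = 0`` keeps exemplar frequency as the tie-break only).

    ``epoch_filter="median"`` additionally discards epochs whose
    clustering correlates with the consensus below the median before
    scoring — useful when sessions contain transient artifacts;
    ``"none"`` (default) retains every epoch.
    """
    if len(clusterings) < 2:
        raise ValueError("need at least 2 epochs to rank channels")
    if len(clusterings) != len(graphs):
        raise ValueError("one graph per clustering required")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    n = len(channel_names)
    Ls = np.stack([cl.L for cl in clusterings]).astype(float)
    M_all = Ls.mean(axis=0)
    m_vec = _offdiag(M_all)
    cons = np.array([_consistency(_offdiag(cl.L), m_vec) for cl in clusterings])
    if epoch_filter == "median":
        med = float(np.median(cons))
        retained = tuple(int(t) for t in np.flatnonzero(cons >= med))
        if not retained:
            warnings.warn("no epoch reached median consistency; retaining all")
            retained = tuple(range(len(clusterings)))
    elif epoch_filter == "none":
        retained = tuple(range(len(clusterings)))
    else:
        raise ValueError(f"unknown epoch_filter {epoch_filter!r}")

    ex_freq = np.zeros(n)
    for t in retained:
        for e in clusterings[t].exemplars:
            ex_freq[e] += 1.0
    ex_freq /= len(retained)

    if delta is not None:
        M = Ls[list(retained)].mean(axis=0)
        S_mean = np.mean([clusterings[t].S for t in retained], axis=0)
        disc = spatial_factor(delta.delta, delta.kappa_max)
        W = M * np.maximum(S_mean, 0.0) * disc
        np.fill_diagonal(W, 0.0)
        # normalize away the montage's deterministic discount footprint:
        # peripheral channels have fewer near (discounted) pairs and would
        # otherwise be favored even on exchangeable null data
        disc_off = disc.copy()
        np.fill_diagonal(disc_off, 0.0)
        footprint = (disc_off ** 2).sum(axis=1)
        footprint = np.where(footprint > 0, footprint, 1.0)
        degree = (W ** 2).sum(axis=1) / footprint
    else:
        degree = np.mean([np.asarray(graphs[t]).sum(axis=1) for t in retained], axis=0)
    if degree.max() > 0:
        degree = degree / degree.max()
    score = alpha * ex_freq + (1.0 - alpha) * degree

    def sort_key(i: int):
        return (-score[i], -ex_freq[i], channel_names[i])

    order_idx = sorted(range(n), key=sort_key)
    return ChannelRanking(
        scores={channel_names[i]: float(score[i]) for i in range(n)},
        order=tuple(channel_names[i] for i in order_idx),
        retained_epochs=retained,
        exemplar_frequency={channel_names[i]: float(ex_freq[i]) for i in range(n)},
        functional_strength={channel_names[i]: float(degree[i]) for i in range(n)},
    )


def aggregate_trial_rankings(orders: list[tuple[str, ...]],
                             best_fraction: float = 0.5) -> tuple[str, ...]:
    """Subject-level order from per-trial orders: mean over each channel's
    *best* half of trial ranks.

    Affective responses are stimulus-selective — a channel that
    co-activates strongly in half the trials and is unremarkable in the
    rest carries signal a plain mean rank would dilute.
    """
    if not orders:
        raise ValueError("no rankings to aggregate")
    names = orders[0]
    n_best = max(int(np.ceil(best_fraction * len(orders))), 1)
    ranks = {name: sorted(order.index(name) for order in orders)[:n_best]
             for name in names}
    mean_best = {name: float(np.mean(v)) for name, v in ranks.items()}
    return tuple(sorted(names, key=lambda name: (mean_best[name], name)))


def select_top_fraction(r: ChannelRanking | tuple[str, ...],
                        fraction: float) -> tuple[str, ...]:
    """The ceil(fraction * C) best-ranked channels."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    order = r.order if isinstance(r, ChannelRanking) else tuple(r)
    n = int(np.ceil(fraction * len(order)))
    return order[:n]


class ChannelSelector:
    """Per-subject channel ranker over the epochs of a whole session.

    ``fit`` accepts the subject's per-trial :class:`FeatureTensor`
    objects.  Within each trial every channel x feature cell is
    standardized across the trial's epochs (co-activation is correlated
    *fluctuation*; this removes each channel's static spectral profile,
    which would otherwise read as spurious persistent similarity
    between unrelated channels).  Each epoch is then clustered with
    affinity propagation on the inter-channel Pearson similarity, and
    one consensus ranking is computed over all epochs of all trials —
    channels that repeatedly co-activate across the session rise to the
    top.  Fitted attributes: ``ranking_`` (channel order, best first),
    ``session_ranking_`` (the full :class:`ChannelRanking`),
    ``trial_rankings_`` (per-trial rankings, for per-stimulus reports),
    ``delta_``.
    """

    def __init__(self, montage: Montage, kappa_max: int = 2, damping: float = 0.9,
                 preference_mode: str = "median", alpha: float = 0.0,
                 epoch_filter: str = "none",
                 max_iter: int = 500, convergence_iter: int = 25):
        self.montage = montage
        self.kappa_max = kappa_max
        self.damping = damping
        self.preference_mode = preference_mode
        self.alpha = alpha
        self.epoch_filter = epoch_filter
        self.max_iter = max_iter
        self.convergence_iter = convergence_iter

    def get_params(self, deep: bool = True) -> dict:
        return dict(montage=self.montage, kappa_max=self.kappa_max,
                    damping=self.damping, preference_mode=self.preference_mode,
                    alpha=self.alpha, epoch_filter=self.epoch_filter,
                    max_iter=self.max_iter, convergence_iter=self.convergence_iter)

    def set_params(self, **params) -> "ChannelSelector":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _preference(self, S: np.ndarray) -> float | None:
        if self.preference_mode == "median":
            return None
        if isinstance(self.preference_mode, str) and self.preference_mode.startswith("fixed:"):
            return float(self.preference_mode[len("fixed:"):])
        raise ValueError(f"unknown preference_mode {self.preference_mode!r}")

    def _epoch_clusterings(self, ft: FeatureTensor, delta: DeltaMatrix):
        mu = ft.values.mean(axis=0)
        sd = ft.values.std(axis=0)
        Z = (ft.values - mu) / np.where(sd > 0, sd, 1.0)
        clusterings, graphs = [], []
        for t in range(ft.n_epochs):
            S = channel_similarity(Z[t], standardize="none")
            cl = affinity_propagation(S, damping=self.damping,
                                      preference=self._preference(S),
                                      max_iter=self.max_iter,
                                      convergence_iter=self.convergence_iter)
            clusterings.append(cl)
            graphs.append(build_coactivation_graph(S, cl.L, delta))
        return clusterings, graphs

    def rank_trial(self, ft: FeatureTensor, delta: DeltaMatrix) -> ChannelRanking:
        clusterings, graphs = self._epoch_clusterings(ft, delta)
        return rank_channels(clusterings, graphs, ft.channel_names,
                             alpha=self.alpha, delta=delta,
                             epoch_filter=self.epoch_filter)

    def fit(self, tensors: list[FeatureTensor]) -> "ChannelSelector":
        if not tensors:
            raise ValueError("need at least one FeatureTensor")
        names = tensors[0].channel_names
        mont = self.montage
        if tuple(mont.names) != tuple(names):
            mont = mont.subset(list(names))
        self.delta_ = neighboring_matrix(mont, self.kappa_max)
        all_cl, all_g = [], []
        self.trial_rankings_ = []
        for ft in tensors:
            cls_, gs = self._epoch_clusterings(ft, self.delta_)
            all_cl.extend(cls_)
            all_g.extend(gs)
            if len(cls_) >= 2:
                self.trial_rankings_.append(
                    rank_channels(cls_, gs, ft.channel_names, alpha=self.alpha,
                                  delta=self.delta_, epoch_filter=self.epoch_filter))
        self.session_ranking_ = rank_channels(
            all_cl, all_g, names, alpha=self.alpha, delta=self.delta_,
            epoch_filter=self.epoch_filter)
        self.ranking_ = self.session_ranking_.order
        return self

    def select(self, fraction: float) -> tuple[str, ...]:
        return select_top_fraction(self.ranking_, fraction)
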