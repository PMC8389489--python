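"""The 54-feature battery computed per epoch per channel.

Seventeen time-domain features (statistical moments, three entropies,
Hjorth mobility/complexity, peak-to-peak, two fractal dimensions,
zero-crossings, line length, decorrelation time, Hurst exponent),
seventeen frequency-domain features (spectral edge frequency, Hjorth
parameters of the power spectrum, a log-log spectral-slope fit, and band
energy / mean band power over the five canonical EEG bands), and twenty
time-frequency features (per-level log energies of a 6-level db4 DWT and
mean/std of the Teager-Kaiser energy operator over the seven sub-band
coefficient sequences).

Degenerate (constant) epochs never produce NaN: variance-normalized
features fall back to 0 and the epoch x channel cell is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy.spatial.distance import pdist

from .recording import EpochedRecording

try:  # optional JIT for the O(n^2) entropy kernels
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "FeatureTensor", "FEATURE_NAMES", "TIME_FEATURES", "FREQ_FEATURES",
    "TIMEFREQ_FEATURES", "band_definition", "extract", "time_domain",
    "freq_domain", "timefreq_domain", "FeatureExtractor",
]

TIME_FEATURES = (
    "mean", "var", "std", "skw", "kurts", "entrpA", "entrpS", "entrpSp",
    "hjorthM", "hjorthC", "ptp", "higuchi", "katz", "zcross", "lnlen",
    "decorr", "hurst",
)
FREQ_FEATURES = (
    "spec_frq", "hjorthMsp", "hjorthCsp",
    "spc_slp1", "spc_slp2", "spc_slp3", "spc_slp4",
    "enrg_bnd1", "enrg_bnd2", "enrg_bnd3", "enrg_bnd4", "enrg_bnd5",
    "powfreq1", "powfreq2", "powfreq3", "powfreq4", "powfreq5",
)
TIMEFREQ_FEATURES = tuple(f"wvlet{i}" for i in range(1, 7)) + tuple(
    f"tk{i}" for i in range(1, 15)
)
FEATURE_NAMES: tuple[str, ...] = TIME_FEATURES + FREQ_FEATURES + TIMEFREQ_FEATURES
assert len(FEATURE_NAMES) == 54

_DWT_LEVELS = 6
_WVLET_LOG_FLOOR = -12.0  # log10 floor for empty sub-bands


def band_definition(fs: float) -> tuple[tuple[str, float, float], ...]:
    """The five canonical bands; gamma's upper edge is Nyquist."""
    nyq = fs / 2.0
    return (
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 12.0, 30.0),
        ("gamma", 30.0, nyq),
    )


@dataclass
class FeatureTensor:
    """``(n_epochs, n_channels, 54)`` feature values with metadata."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    channel_names: tuple[str, ...]
    fs: float
    w: float
    band_edges: tuple[tuple[str, float, float], ...]
    flags: np.ndarray  # (n_epochs, n_channels) bool: degenerate input
    subject_id: str = ""
    trial_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]


# ---------------------------------------------------------------------------
# helpers

def _welch(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(len(x), 256)
    return sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                     noverlap=nperseg // 2)


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = len(x) - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def _phi_counts_numpy(x: np.ndarray, m: int, r: float) -> np.ndarray:
    emb = _embed(x, m)
    nv = len(emb)
    d = pdist(emb, metric="chebyshev")
    counts = np.ones(nv)  # self-match
    idx = np.flatnonzero(d <= r)
    # invert the condensed pdist index: idx -> (i, j), i < j
    i = (nv - 2 - np.floor(
        np.sqrt(-8 * idx + 4 * nv * (nv - 1) - 7) / 2.0 - 0.5)).astype(int)
    j = (idx + i + 1 - nv * (nv - 1) // 2 + (nv - i) * ((nv - i) - 1) // 2).astype(int)
    np.add.at(counts, i, 1)
    np.add.at(counts, j, 1)
    return counts


if _njit is not None:

    @_njit
    def _entropy_counts_jit(x, m, r):  # pragma: no cover - exercised via _apen
        """Chebyshev template-match counts for orders m and m+1.

        Returns (apen counts m, apen counts m+1, sampen B, sampen A):
        approximate-entropy counts include the self-match over the
        n-m+1 (order m) and n-m (order m+1) templates; the sample
        entropy pair counts B and A exclude self-matches and both run
        over the common n-m templates.
        """
        n = len(x)
        nv1 = n - m + 1
        nv2 = n - m
        c1 = np.ones(nv1)
        c2 = np.ones(nv2)
        b = 0
        a = 0
        for i in range(nv1):
            for j in range(i + 1, nv1):
                d_m = 0.0
                for k in range(m):
                    d = abs(x[i + k] - x[j + k])
                    if d > d_m:
                        d_m = d
                if d_m <= r:
                    c1[i] += 1.0
                    c1[j] += 1.0
                if j < nv2:
                    if d_m <= r:
                        b += 1
                    d_m1 = abs(x[i + m] - x[j + m])
                    if d_m1 < d_m:
                        d_m1 = d_m
                    if d_m1 <= r:
                        c2[i] += 1.0
                        c2[j] += 1.0
                        a += 1
        return c1, c2, b, a
else:  # pragma: no cover
    _entropy_counts_jit = None


def _entropies(x: np.ndarray, m: int = 2,
               r: float | None = None) -> tuple[float, float]:
    """(approximate entropy, sample entropy) with shared template counts."""
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        return 0.0, 0.0
    if _entropy_counts_jit is not None:
        c1, c2, b, a = _entropy_counts_jit(np.ascontiguousarray(x, dtype=np.float64),
                                           m, float(r))
        nv1, nv2 = len(c1), len(c2)
        apen = float(np.mean(np.log(c1 / nv1)) - np.mean(np.log(c2 / nv2)))
        sampen = float(-np.log(a / b)) if a > 0 and b > 0 else 0.0
        return apen, sampen
    c1 = _phi_counts_numpy(x, m, r)
    c2 = _phi_counts_numpy(x, m + 1, r)
    apen = float(np.mean(np.log(c1 / len(c1))) - np.mean(np.log(c2 / len(c2))))
    ns = len(x) - m
    emb_m = _embed(x, m)[:ns]
    emb_m1 = _embed(x, m + 1)[:ns]
    b = int(np.count_nonzero(pdist(emb_m, metric="chebyshev") <= r))
    a = int(np.count_nonzero(pdist(emb_m1, metric="chebyshev") <= r))
    sampen = float(-np.log(a / b)) if a > 0 and b > 0 else 0.0
    return apen, sampen


def _apen(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (self-matches included, Chebyshev distance)."""
    return _entropies(x, m, r)[0]


def _sampen(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy (self-matches excluded)."""
    return _entropies(x, m, r)[1]


def _spectral_entropy(psd: np.ndarray) -> float:
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd[psd > 0] / total
    return float(-(p * np.log2(p)).sum())


def _hjorth(x: np.ndarray) -> tuple[float, float]:
    v0 = np.var(x)
    if v0 == 0:
        return 0.0, 0.0
    d1 = np.diff(x)
    v1 = np.var(d1)
    mob = np.sqrt(v1 / v0)
    if v1 == 0:
        return float(mob), 0.0
    v2 = np.var(np.diff(d1))
    mob_d = np.sqrt(v2 / v1)
    return float(mob), float(mob_d / mob) if mob > 0 else 0.0


def _higuchi_curve(x: np.ndarray, k_max: int) -> tuple[list, list]:
    n = len(x)
    lk, ks = [], []
    for k in range(1, k_max + 1):
        d = np.abs(x[k:] - x[:-k])  # |x[i+k] - x[i]| for every start i
        lengths = []
        for m in range(k):
            seg = d[m::k]
            n_m = len(seg) + 1  # points in the subsampled series
            if n_m < 2:
                continue
            norm = (n - 1) / ((n_m - 1) * k)
            lengths.append(seg.sum() * norm / k)
        if lengths:
            mean_l = float(np.mean(lengths))
            if mean_l > 0:
                lk.append(np.log(mean_l))
                ks.append(np.log(1.0 / k))
    return ks, lk


if _njit is not None:

    @_njit
    def _higuchi_curve_jit(x, k_max):  # pragma: no cover - via _higuchi
        n = len(x)
        lk = []
        ks = []
        for k in range(1, k_max + 1):
            total = 0.0
            n_curves = 0
            for m in range(k):
                n_m = (n - 1 - m) // k + 1
                if n_m < 2:
                    continue
                dist = 0.0
                for i in range(m + k, n, k):
                    dist += abs(x[i] - x[i - k])
                total += dist * (n - 1) / ((n_m - 1) * k) / k
                n_curves += 1
            if n_curves > 0:
                mean_l = total / n_curves
                if mean_l > 0:
                    lk.append(np.log(mean_l))
                    ks.append(np.log(1.0 / k))
        return ks, lk
else:  # pragma: no cover
    _higuchi_curve_jit = None


def _slope(xs, ys) -> float:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    xc = xs - xs.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return 0.0
    return float(xc @ (ys - ys.mean()) / denom)


def _higuchi(x: np.ndarray, k_max: int = 10) -> float:
    if _higuchi_curve_jit is not None:
        ks, lk = _higuchi_curve_jit(np.ascontiguousarray(x, dtype=np.float64), k_max)
    else:
        ks, lk = _higuchi_curve(x, k_max)
    if len(lk) < 2:
        return 0.0
    return _slope(ks, lk)


def _katz(x: np.ndarray) -> float:
    diffs = np.abs(np.diff(x))
    L = diffs.sum()
    if L == 0:
        return 0.0
    d = np.abs(x - x[0]).max()
    if d == 0:
        return 0.0
    n = len(x) - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x - x.mean())
    s = s[s != 0]  # exact zeros counted once via the surrounding sign change
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(np.diff(s)))


def _decorrelation_time(x: np.ndarray, fs: float) -> float:
    xc = x - x.mean()
    v = np.dot(xc, xc)
    if v == 0:
        return 0.0
    n = len(xc)
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n] / v
    below = np.flatnonzero(acf < 1.0 / np.e)
    lag = int(below[0]) if len(below) else n - 1
    return lag / fs


def _hurst_curve(x: np.ndarray, sizes) -> tuple[list, list]:
    n = len(x)
    log_rs, log_n = [], []
    for size in sizes:
        k = n // size
        seg = x[: k * size].reshape(k, size)
        dev = seg - seg.mean(axis=1, keepdims=True)
        z = np.cumsum(dev, axis=1)
        r = z.max(axis=1) - z.min(axis=1)
        s = seg.std(axis=1)
        ok = s > 0
        if ok.any():
            log_rs.append(float(np.log(np.mean(r[ok] / s[ok]))))
            log_n.append(float(np.log(size)))
    return log_n, log_rs


if _njit is not None:

    @_njit
    def _hurst_curve_jit(x, sizes):  # pragma: no cover - via _hurst_rs
        n = len(x)
        log_rs = []
        log_n = []
        for size in sizes:
            k = n // size
            total = 0.0
            count = 0
            for seg_i in range(k):
                start = seg_i * size
                mean = 0.0
                for i in range(start, start + size):
                    mean += x[i]
                mean /= size
                z = 0.0
                zmin = 0.0
                zmax = 0.0
                ss = 0.0
                for i in range(start, start + size):
                    d = x[i] - mean
                    ss += d * d
                    z += d
                    if z < zmin:
                        zmin = z
                    if z > zmax:
                        zmax = z
                s = np.sqrt(ss / size)
                if s > 0:
                    total += (zmax - zmin) / s
                    count += 1
            if count > 0:
                log_rs.append(np.log(total / count))
                log_n.append(np.log(size))
        return log_n, log_rs
else:  # pragma: no cover
    _hurst_curve_jit = None


def _hurst_rs(x: np.ndarray) -> float:
    n = len(x)
    sizes = []
    size = 8
    while size <= n // 2:
        sizes.append(size)
        size *= 2
    if len(sizes) < 2:
        return 0.5
    if _hurst_curve_jit is not None:
        log_n, log_rs = _hurst_curve_jit(
            np.ascontiguousarray(x, dtype=np.float64),
            np.asarray(sizes, dtype=np.int64))
    else:
        log_n, log_rs = _hurst_curve(x, sizes)
    if len(log_rs) < 2:
        return 0.5
    return _slope(log_n, log_rs)


# ---------------------------------------------------------------------------
# feature groups

def time_domain(x: np.ndarray, fs: float,
                psd: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """The 17 time-domain features of one single-channel epoch."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("epoch too short for time-domain features")
    if psd is None:
        psd = _welch(x, fs)
    _, pxx = psd
    var = float(np.var(x, ddof=1))
    degenerate = var == 0
    out = np.zeros(len(TIME_FEATURES))
    out[0] = float(x.mean())
    out[1] = var
    out[2] = np.sqrt(var)
    if not degenerate:
        xc = x - x.mean()
        m2 = np.mean(xc ** 2)
        out[3] = float(np.mean(xc ** 3) / m2 ** 1.5)
        out[4] = float(np.mean(xc ** 4) / m2 ** 2 - 3.0)  # excess: normal -> 0
        out[5], out[6] = _entropies(x)
        out[7] = _spectral_entropy(pxx)
        out[8], out[9] = _hjorth(x)
        out[10] = float(np.ptp(x))
        out[11] = _higuchi(x)
        out[12] = _katz(x)
        out[13] = _zero_crossings(x)
        out[14] = float(np.abs(np.diff(x)).sum())
        out[15] = _decorrelation_time(x, fs)
        out[16] = _hurst_rs(x)
    return out


def freq_domain(x: np.ndarray, fs: float,
                bands: tuple[tuple[str, float, float], ...] | None = None,
                psd: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """The 17 frequency-domain features of one single-channel epoch."""
    x = np.asarray(x, dtype=float)
    if bands is None:
        bands = band_definition(fs)
    if psd is None:
        psd = _welch(x, fs)
    freqs, pxx = psd
    out = np.zeros(len(FREQ_FEATURES))
    total = pxx.sum()
    if total <= 0:
        return out
    # spectral edge frequency at 95% cumulative power
    cum = np.cumsum(pxx)
    out[0] = float(freqs[np.searchsorted(cum, 0.95 * cum[-1])])
    # Hjorth parameters applied to the PSD sequence
    out[1], out[2] = _hjorth(pxx)
    # log-log spectral slope over 1-40 Hz
    mask = (freqs >= 1.0) & (freqs <= 40.0) & (pxx > 0)
    if mask.sum() >= 3:
        lx = np.log10(freqs[mask])
        ly = np.log10(pxx[mask])
        slope = _slope(lx, ly)
        intercept = float(ly.mean() - slope * lx.mean())
        resid = ly - (intercept + slope * lx)
        mse = float(np.mean(resid ** 2))
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
        out[3], out[4], out[5], out[6] = float(intercept), float(slope), mse, r2
    # band energy (trapezoidal PSD integral) and mean band power
    for b, (_, lo, hi) in enumerate(bands):
        sel = (freqs >= lo) & (freqs <= hi)
        if sel.sum() >= 2:
            out[7 + b] = float(np.trapezoid(pxx[sel], freqs[sel]))
        if sel.any():
            out[12 + b] = float(pxx[sel].mean())
    return out


def timefreq_domain(x: np.ndarray, fs: float) -> np.ndarray:
    """The 20 wavelet features: 6 log sub-band energies + 14 TK stats.

    The 6-level db4 DWT yields sub-bands D1..D6 and A6; each of the 7
    coefficient sequences contributes the mean and standard deviation of
    the Teager-Kaiser energy psi[c_n] = c_n^2 - c_{n-1} c_{n+1}, giving
    (levels + 1) * 2 = 14 TK features ordered D1.mean, D1.std, ...,
    D6.mean, D6.std, A6.mean, A6.std.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 ** _DWT_LEVELS:
        raise ValueError(f"epoch shorter than 2^{_DWT_LEVELS} samples")
    with warnings.catch_warnings():
        # short epochs make level 6 boundary-dominated; that is accepted
        warnings.filterwarnings("ignore", message="Level value .* is too high")
        coeffs = pywt.wavedec(x, "db4", mode="symmetric", level=_DWT_LEVELS)
    approx, details_desc = coeffs[0], coeffs[1:]  # details: D6 .. D1
    details = details_desc[::-1]  # D1 .. D6
    out = np.zeros(len(TIMEFREQ_FEATURES))
    for lvl, d in enumerate(details):
        ms = float(np.mean(d ** 2)) if len(d) else 0.0
        out[lvl] = np.log10(max(ms, 10.0 ** _WVLET_LOG_FLOOR))
    subbands = list(details) + [approx]
    for k, c in enumerate(subbands):
        if len(c) < 3:
            continue
        psi = c[1:-1] ** 2 - c[:-2] * c[2:]
        out[6 + 2 * k] = float(psi.mean())
        out[6 + 2 * k + 1] = float(psi.std())
    return out


def _extract_one(x: np.ndarray, fs: float,
                 bands: tuple[tuple[str, float, float], ...]) -> tuple[np.ndarray, bool]:
    psd = _welch(x, fs)
    degenerate = np.var(x) == 0
    vec = np.concatenate([
        time_domain(x, fs, psd=psd),
        freq_domain(x, fs, bands=bands, psd=psd),
        timefreq_domain(x, fs),
    ])
    return np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0), bool(degenerate)


def _timefreq_batch(flat: np.ndarray) -> np.ndarray:
    """Vectorized :func:`timefreq_domain` over rows of ``flat``."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Level value .* is too high")
        coeffs = pywt.wavedec(flat, "db4", mode="symmetric",
                              level=_DWT_LEVELS, axis=-1)
    approx, details = coeffs[0], coeffs[1:][::-1]  # D1 .. D6
    out = np.zeros((flat.shape[0], len(TIMEFREQ_FEATURES)))
    floor = 10.0 ** _WVLET_LOG_FLOOR
    for lvl, d in enumerate(details):
        ms = np.mean(d ** 2, axis=-1) if d.shape[-1] else np.zeros(flat.shape[0])
        out[:, lvl] = np.log10(np.maximum(ms, floor))
    for k, c in enumerate(list(details) + [approx]):
        if c.shape[-1] < 3:
            continue
        psi = c[:, 1:-1] ** 2 - c[:, :-2] * c[:, 2:]
        out[:, 6 + 2 * k] = psi.mean(axis=-1)
        out[:, 6 + 2 * k + 1] = psi.std(axis=-1)
    return out


def extract(ep: EpochedRecording) -> FeatureTensor:
    """Compute all 54 features for every epoch x channel."""
    n_samp = ep.epochs.shape[2]
    if n_samp < 128:
        raise ValueError("epochs must be at least 128 samples for a 6-level DWT")
    bands = band_definition(ep.fs)
    flat = ep.epochs.reshape(-1, n_samp)
    # batch the PSD and the DWT over all epoch x channel rows at once
    nperseg = min(n_samp, 256)
    freqs, pxx_all = sps.welch(flat, fs=ep.fs, window="hamming",
                               nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    tf_all = _timefreq_batch(flat)
    n_tf = len(TIMEFREQ_FEATURES)
    values = np.empty((flat.shape[0], len(FEATURE_NAMES)))
    flags = np.zeros(flat.shape[0], dtype=bool)
    for i, x in enumerate(flat):
        psd = (freqs, pxx_all[i])
        degenerate = np.var(x) == 0
        vec = np.concatenate([
            time_domain(x, ep.fs, psd=psd),
            freq_domain(x, ep.fs, bands=bands, psd=psd),
            tf_all[i],
        ])
        values[i] = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
        flags[i] = degenerate
    values = values.reshape(ep.n_epochs, ep.n_channels, -1)
    flags = flags.reshape(ep.n_epochs, ep.n_channels)
    assert values.shape[2] == 34 + n_tf
    return FeatureTensor(
        values=values, feature_names=FEATURE_NAMES,
        channel_names=ep.channel_names, fs=ep.fs, w=ep.w,
        band_edges=bands, flags=flags,
        subject_id=ep.subject_id, trial_id=ep.trial_id,
    )


class FeatureExtractor:
    """Thin transformer wrapper around :func:`extract`."""

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self) -> "FeatureExtractor":
        return self

    def transform(self, ep: EpochedRecording) -> FeatureTensor:
        return extract(ep)

    def __call__(self, ep: EpochedRecording) -> FeatureTensor:
        return extract(ep)
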