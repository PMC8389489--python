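"""Artifact reduction and epoching.

The processing order is fixed: 50 Hz notch -> 0.5-40 Hz band-pass ->
ICA-based ocular-component removal -> down-sampling to 128 Hz ->
segmentation into non-overlapping windows of ``w`` seconds.  All filters
are zero-phase (forward-backward IIR), so pass-band components keep their
timing; down-sampling is polyphase so non-integer rate ratios work.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .recording import EpochedRecording, Recording

__all__ = [
    "notch_filter", "bandpass_filter", "remove_ocular", "downsample",
    "epoch", "Preprocessor",
]

#: ICA components are rejected when |Pearson r| with the ocular reference
#: exceeds this; at most _MAX_REJECT_FRAC of components may be removed.
_REJECT_R = 0.7
_MAX_REJECT_FRAC = 0.3


def notch_filter(rec: Recording, freq: float = 50.0, quality: float = 30.0) -> Recording:
    """Zero-phase band-stop at ``freq`` Hz (power-line noise)."""
    nyq = rec.fs / 2.0
    if freq >= nyq:
        raise ValueError(f"notch frequency {freq} Hz >= Nyquist {nyq} Hz")
    b, a = sps.iirnotch(freq, quality, fs=rec.fs)
    out = sps.filtfilt(b, a, rec.samples, axis=1)
    return rec.with_samples(out, step=f"notch@{freq}Hz")


def bandpass_filter(rec: Recording, lo: float = 0.5, hi: float = 40.0,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (default 0.5-40 Hz)."""
    nyq = rec.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band [{lo}, {hi}] must satisfy 0 < lo < hi < Nyquist ({nyq})")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.with_samples(out, step=f"bandpass@{lo}-{hi}Hz")


def _ocular_reference(rec: Recording) -> np.ndarray:
    """Bipolar EOG reference, or the prefrontal mean when no EOG exists."""
    if len(rec.eog_channels) >= 2:
        i = rec.channel_names.index(rec.eog_channels[0])
        j = rec.channel_names.index(rec.eog_channels[1])
        return rec.samples[i] - rec.samples[j]
    if len(rec.eog_channels) == 1:
        return rec.samples[rec.channel_names.index(rec.eog_channels[0])]
    prefrontal = [i for i, n in enumerate(rec.channel_names) if n in ("Fp1", "Fp2")]
    if not prefrontal:
        raise ValueError("no EOG channels and no prefrontal (Fp1/Fp2) channels to reference")
    return rec.samples[prefrontal].mean(axis=0)


def remove_ocular(rec: Recording, threshold: float = _REJECT_R,
                  random_state: int = 0) -> Recording:
    """Zero ICA components that track the ocular reference, then rebuild.

    Scalp channels are decomposed with FastICA (as many components as
    scalp channels); components whose time course correlates with the
    bipolar EOG reference (or, without EOG, the Fp1/Fp2 mean) at
    ``|r| >= threshold`` are zeroed, capped at 30% of components.  On
    ICA non-convergence the input is returned unchanged with a warning.
    """
    scalp_idx = [i for i, n in enumerate(rec.channel_names) if n not in rec.eog_channels]
    if len(scalp_idx) < 8:
        raise ValueError(f"need >= 8 scalp channels for ICA, got {len(scalp_idx)}")
    ref = _ocular_reference(rec)
    X = rec.samples[scalp_idx].T  # samples x channels
    # deflation extracts components one at a time and converges on mixtures
    # whose bulk is near-Gaussian, where the parallel update stalls
    ica = FastICA(n_components=len(scalp_idx), random_state=random_state,
                  algorithm="deflation", max_iter=500, tol=1e-3,
                  whiten="unit-variance")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            sources = ica.fit_transform(X)
        except Exception as exc:  # pragma: no cover - FastICA rarely raises
            warnings.warn(f"ICA failed ({exc}); returning input unchanged")
            return rec.with_samples(rec.samples, step="ica:failed")
        converged = not any("did not converge" in str(w.message) for w in caught)
    if not converged:
        warnings.warn("FastICA did not converge; returning input unchanged")
        return rec.with_samples(rec.samples, step="ica:nonconverged")

    ref_c = ref - ref.mean()
    ref_sd = ref_c.std()
    if ref_sd == 0:
        return rec.with_samples(rec.samples, step="ica:flat-reference")
    src_c = sources - sources.mean(axis=0)
    denom = src_c.std(axis=0) * ref_sd * len(ref)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, src_c.T @ ref_c / denom, 0.0)
    candidates = np.flatnonzero(np.abs(r) >= threshold)
    max_reject = int(np.floor(_MAX_REJECT_FRAC * len(scalp_idx)))
    if len(candidates) > max_reject:
        candidates = candidates[np.argsort(-np.abs(r[candidates]))][:max_reject]
    if len(candidates) == 0:
        return rec.with_samples(rec.samples, step="ica:none-rejected")
    sources[:, candidates] = 0.0
    cleaned = ica.inverse_transform(sources).T
    out = rec.samples.copy()
    out[scalp_idx] = cleaned
    return rec.with_samples(out, step=f"ica:rejected={len(candidates)}")


def downsample(rec: Recording, fs_out: float = 128.0) -> Recording:
    """Polyphase resampling to ``fs_out`` (identity when rates match)."""
    if fs_out > rec.fs:
        raise ValueError(f"fs_out={fs_out} exceeds input rate {rec.fs}")
    if fs_out == rec.fs:
        return rec.with_samples(rec.samples, step="downsample:identity")
    ratio = Fraction(fs_out / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=1)
    return rec.with_samples(out, fs=fs_out, step=f"downsample@{fs_out}Hz")


def epoch(rec: Recording, w: float) -> EpochedRecording:
    """Cut into consecutive non-overlapping ``w``-second windows."""
    n_per = w * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(f"w*fs = {n_per} is not an integer sample count")
    n_per = int(round(n_per))
    if n_per > rec.n_samples:
        raise ValueError(
            f"window of {w} s ({n_per} samples) exceeds recording length {rec.n_samples}"
        )
    n_ep = rec.n_samples // n_per
    data = rec.samples[:, : n_ep * n_per]
    epochs = data.reshape(rec.n_channels, n_ep, n_per).transpose(1, 0, 2)
    return EpochedRecording(
        epochs=epochs, w=w, fs=rec.fs, channel_names=rec.channel_names,
        subject_id=rec.subject_id, trial_id=rec.trial_id,
        provenance=rec.provenance + (f"epoch@{w}s",),
    )


class Preprocessor:
    """The fixed preprocessing chain as a configurable transformer.

    Parameters mirror the individual steps; ``transform`` applies
    notch -> band-pass -> (optional) ocular ICA -> down-sample -> epoch
    and returns an :class:`EpochedRecording` restricted to scalp
    channels.
    """

    def __init__(self, notch_hz: float = 50.0, band: tuple[float, float] = (0.5, 40.0),
                 fs_out: float = 128.0, w: float = 2.0, ica: bool = True,
                 random_state: int = 0):
        self.notch_hz = notch_hz
        self.band = band
        self.fs_out = fs_out
        self.w = w
        self.ica = ica
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return dict(notch_hz=self.notch_hz, band=self.band, fs_out=self.fs_out,
                    w=self.w, ica=self.ica, random_state=self.random_state)

    def set_params(self, **params) -> "Preprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def preprocess_continuous(self, rec: Recording) -> Recording:
        """The filter chain without epoching; EOG channels dropped at the end."""
        out = notch_filter(rec, self.notch_hz)
        out = bandpass_filter(out, *self.band)
        if self.ica:
            out = remove_ocular(out, random_state=self.random_state)
        out = downsample(out, self.fs_out)
        if out.eog_channels:
            scalp = [i for i, n in enumerate(out.channel_names)
                     if n not in out.eog_channels]
            out = Recording(
                samples=out.samples[scalp], fs=out.fs,
                channel_names=tuple(out.channel_names[i] for i in scalp),
                subject_id=out.subject_id, trial_id=out.trial_id,
                provenance=out.provenance + ("drop-eog",),
            )
        return out

    def transform(self, rec: Recording) -> EpochedRecording:
        return epoch(self.preprocess_continuous(rec), self.w)

    def __call__(self, rec: Recording) -> EpochedRecording:
        return self.transform(rec)
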