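"""Synthetic multi-subject EEG with planted, recoverable class structure.

The generator emulates the structure of affective-EEG benchmarks (many
subjects x many trials x a 10-20 montage of channels x a continuous
voltage trace, plus per-trial self-reported valence/arousal ratings on a
1-9 scale) without any physiological forward modeling.  Each channel
carries

* a 1/f^alpha "pink" background (unit variance),
* one random-phase sinusoid per canonical EEG band (delta, theta, alpha,
  beta, gamma), each under an independent slowly varying lognormal
  amplitude envelope (~1 s timescale) emulating the burst-like
  nonstationarity of real band power,
* a common-phase 50 Hz line-noise sinusoid,
* frontally-dominant eye-blink transients (300 ms raised-cosine biphasic
  pulses) mirrored into two synthetic EOG reference channels.

The class signal is a *coherent* band activation of the informative
channels on trials whose (valence) class is "high": their
informative-band sinusoids share one common amplitude envelope (the
signature of event-related co-activation across involved sites), and
the Fourier content of those channels inside the informative bands is
scaled by ``sqrt(effect_size)``, so the band-power ratio between
classes equals ``effect_size`` by construction.  With
``effect_size = 1`` no structure of any kind is planted and all
channels are exchangeable.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage, load_montage
from .recording import Recording

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset", "BAND_EDGES"]

#: Canonical band edges used for planting effects (gamma runs to Nyquist).
BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, None),  # None -> Nyquist
}

_EOG_NAMES = ("EOG1", "EOG2")


@dataclass
class SynthConfig:
    """Parameters of one synthetic study.

    ``effect_size`` is the high/low class ratio of band power in the
    informative channels/bands; 1.0 means no planted signal.
    """

    n_subjects: int = 4
    n_trials: int = 8
    n_channels: int = 32
    montage: str = "standard_1020_32"
    fs_raw: float = 512.0
    duration: float = 60.0
    informative_channels: tuple[str, ...] = ("F3", "F4", "T7")
    informative_bands: tuple[str, ...] = ("alpha",)
    effect_size: float = 3.0
    line_noise_amp: float = 0.5
    blink_rate: float = 15.0  # events per minute
    blink_amp: float = 10.0
    noise_spectrum_exponent: float = 1.0
    band_sine_amp: float = 1.0
    include_eog: bool = True
    seed: int = 0

    def validate(self, montage: Montage) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be positive")
        if self.n_channels < 4:
            raise ValueError("need at least 4 channels")
        if self.n_channels > len(montage):
            raise ValueError(
                f"n_channels={self.n_channels} exceeds montage size {len(montage)}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs_raw <= 0:
            raise ValueError("fs_raw must be positive")
        if self.blink_rate < 0 or self.line_noise_amp < 0:
            raise ValueError("rates and amplitudes must be non-negative")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        n = self.duration * self.fs_raw
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs_raw must be an integer sample count")
        names = montage.names[: self.n_channels]
        missing = set(self.informative_channels) - set(names)
        if missing:
            raise ValueError(f"informative channels not in channel set: {sorted(missing)}")
        unknown = set(self.informative_bands) - set(BAND_EDGES)
        if unknown:
            raise ValueError(f"unknown bands: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted: informative channels, labels, and effect map."""

    informative_channels: frozenset[str]
    labels: pd.DataFrame  # subject_id, trial_id, valence/arousal class+rating
    planted_effect: dict[tuple[str, str], float] = field(default_factory=dict)

    def label(self, subject_id: str, trial_id: str, target: str = "valence") -> int:
        row = self.labels[(self.labels.subject_id == subject_id)
                          & (self.labels.trial_id == trial_id)]
        return int(row[f"{target}_class"].iloc[0])


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with PSD proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.empty_like(freqs)
    shape[0] = 0.0  # zero-mean
    with np.errstate(divide="ignore"):
        shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _amplitude_envelope(rng: np.random.Generator, n: int, fs: float,
                        node_spacing: float = 1.0, sigma: float = 0.6) -> np.ndarray:
    """Positive mean-1 lognormal envelope with ~`node_spacing`-second structure."""
    n_nodes = max(int(np.ceil(n / (node_spacing * fs))) + 1, 2)
    g = rng.standard_normal(n_nodes)
    nodes = np.exp(sigma * g - sigma ** 2 / 2.0)
    pos = np.arange(n) / (node_spacing * fs)
    return np.interp(pos, np.arange(n_nodes), nodes)


def _blink_pulse(fs: float, width: float = 0.3) -> np.ndarray:
    """Biphasic raised-cosine pulse: one sine cycle under a Hann envelope."""
    n = max(int(round(width * fs)), 4)
    t = np.arange(n) / n
    return np.sin(2 * np.pi * t) * 0.5 * (1 - np.cos(2 * np.pi * t))


def _band_slice(band: str, nyq: float):
    lo, hi = BAND_EDGES[band]
    return lo, (nyq if hi is None else min(hi, nyq))


def _balanced_classes(rng: np.random.Generator, n: int) -> np.ndarray:
    half = n // 2
    labels = np.array([1] * half + [0] * (n - half))
    rng.shuffle(labels)
    return labels


def _balanced_label_matrix(rng: np.random.Generator, n_subjects: int,
                           n_trials: int, max_tries: int = 200) -> np.ndarray:
    """(subjects x trials) binary labels balanced along both margins.

    Each subject's trials are half high / half low, and each stimulus
    draws a near-balanced response across subjects (prevalence within
    [0.4, 0.6]) — benchmark stimulus sets are deliberately curated to
    cover both ends of the affect scales.  Falls back to per-subject
    balance only if the joint constraint cannot be met (tiny designs).
    """
    lo = int(np.ceil(n_subjects * 0.4))
    hi = int(np.floor(n_subjects * 0.6))
    while True:
        for _ in range(max_tries):
            m = np.stack([_balanced_classes(rng, n_trials)
                          for _ in range(n_subjects)])
            col = m.sum(axis=0)
            if n_subjects < 4 or np.all((col >= lo) & (col <= hi)):
                return m
        # the tight band can be infeasible for small designs: widen and retry
        lo, hi = lo - 1, hi + 1
        if lo <= 0:
            return m


def generate_dataset(config: SynthConfig) -> tuple[list[Recording], GroundTruth]:
    """Generate all subject x trial recordings plus the ground truth.

    Returns a flat list ordered subject-major (``s000/t000, s000/t001,
    ...``) — group on ``subject_id`` to recover the per-subject structure.
    """
    montage = load_montage(config.montage)
    config.validate(montage)
    scalp_names = montage.names[: config.n_channels]
    sub_montage = montage.subset(list(scalp_names)) if config.n_channels < len(montage) else montage
    rng = np.random.default_rng(config.seed)

    n = int(round(config.duration * config.fs_raw))
    fs = config.fs_raw
    nyq = fs / 2.0
    t = np.arange(n) / fs
    freqs = np.fft.rfftfreq(n, 1.0 / fs)

    # blink amplitude decays with distance from the frontal pole; the most
    # frontal scalp channel receives the full blink_amp (real blinks dominate
    # prefrontal EEG by severalfold)
    xy = sub_montage.positions
    front = xy[:, 1].max()
    frontal_pole = np.array([0.0, front])
    d_front = np.linalg.norm(xy - frontal_pole, axis=1)
    blink_gain = np.exp(-(d_front - d_front.min()) / 0.6)

    informative_idx = [scalp_names.index(c) for c in config.informative_channels]
    band_masks = {}
    for band in config.informative_bands:
        lo, hi = _band_slice(band, nyq)
        band_masks[band] = (freqs >= lo) & (freqs < hi)

    val_matrix = _balanced_label_matrix(rng, config.n_subjects, config.n_trials)
    aro_matrix = _balanced_label_matrix(rng, config.n_subjects, config.n_trials)

    recordings: list[Recording] = []
    rows = []
    for s in range(config.n_subjects):
        sid = f"s{s:03d}"
        val = val_matrix[s]
        aro = aro_matrix[s]
        for tr in range(config.n_trials):
            tid = f"t{tr:03d}"
            v_cls, a_cls = int(val[tr]), int(aro[tr])
            v_rate = rng.uniform(6, 9) if v_cls else rng.uniform(1, 4)
            a_rate = rng.uniform(6, 9) if a_cls else rng.uniform(1, 4)
            rows.append(dict(subject_id=sid, trial_id=tid,
                             valence_class=v_cls, arousal_class=a_cls,
                             valence_rating=v_rate, arousal_rating=a_rate))

            planted_trial = config.effect_size != 1.0 and v_cls == 1
            # one shared envelope per informative band: co-activation of the
            # informative channels on "high" trials
            shared_env = {band: _amplitude_envelope(rng, n, fs)
                          for band in config.informative_bands}
            sig = np.empty((config.n_channels, n))
            for c in range(config.n_channels):
                x = _pink_noise(rng, n, fs, config.noise_spectrum_exponent)
                for band in BAND_EDGES:
                    lo, hi = _band_slice(band, nyq)
                    f0 = rng.uniform(lo, max(hi - 1e-6, lo))
                    ph = rng.uniform(0, 2 * np.pi)
                    if planted_trial and c in informative_idx and band in shared_env:
                        env = shared_env[band]
                    else:
                        env = _amplitude_envelope(rng, n, fs)
                    x = x + config.band_sine_amp * env * np.sin(2 * np.pi * f0 * t + ph)
                if planted_trial and c in informative_idx:
                    spec = np.fft.rfft(x)
                    for band in config.informative_bands:
                        spec[band_masks[band]] *= np.sqrt(config.effect_size)
                    x = np.fft.irfft(spec, n=n)
                sig[c] = x

            # line noise: common phase across the cap
            if config.line_noise_amp > 0 and nyq > 50.0:
                ph = rng.uniform(0, 2 * np.pi)
                sig += config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + ph)

            # blinks, mirrored into the EOG pair
            pulse = _blink_pulse(fs)
            blink_trace = np.zeros(n)
            n_blinks = rng.poisson(config.blink_rate * config.duration / 60.0)
            for _ in range(n_blinks):
                start = rng.integers(0, max(n - len(pulse), 1))
                blink_trace[start:start + len(pulse)] += pulse[: n - start]
            sig += config.blink_amp * blink_gain[:, None] * blink_trace[None, :]

            names = list(scalp_names)
            eog: tuple[str, ...] = ()
            if config.include_eog:
                eog1 = config.blink_amp * blink_trace + 0.1 * rng.standard_normal(n)
                eog2 = -0.5 * config.blink_amp * blink_trace + 0.1 * rng.standard_normal(n)
                sig = np.vstack([sig, eog1, eog2])
                names += list(_EOG_NAMES)
                eog = _EOG_NAMES
            recordings.append(Recording(
                samples=sig, fs=fs, channel_names=tuple(names), eog_channels=eog,
                subject_id=sid, trial_id=tid, provenance=("synth",),
            ))

    planted = {}
    if config.effect_size != 1.0:
        for band in config.informative_bands:
            for ch in config.informative_channels:
                planted[(band, ch)] = config.effect_size
    truth = GroundTruth(
        informative_channels=frozenset(config.informative_channels),
        labels=pd.DataFrame(rows),
        planted_effect=planted,
    )
    return recordings, truth
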