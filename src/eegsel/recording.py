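"""In-memory containers for continuous and epoched multichannel EEG."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "EpochedRecording"]


@dataclass
class Recording:
    """A continuous multichannel voltage trace.

    Attributes
    ----------
    samples
        ``(n_channels, n_samples)`` float array, scalp channels first and
        any EOG reference channels last (their names listed in
        ``eog_channels``).
    fs
        Sampling rate in Hz.
    channel_names
        One unique name per row of ``samples``.
    eog_channels
        Names of the ocular reference channels (subset of
        ``channel_names``); all remaining channels are scalp channels.
    provenance
        Append-only log of the processing steps applied so far.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    eog_channels: tuple[str, ...] = ()
    subject_id: str = ""
    trial_id: str = ""
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        self.eog_channels = tuple(self.eog_channels)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        unknown = set(self.eog_channels) - set(self.channel_names)
        if unknown:
            raise ValueError(f"EOG channels not present in data: {sorted(unknown)}")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain NaN or Inf")

    # -- convenience -----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(n for n in self.channel_names if n not in self.eog_channels)

    def scalp_data(self) -> np.ndarray:
        idx = [i for i, n in enumerate(self.channel_names) if n not in self.eog_channels]
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray, *, fs: float | None = None,
                     step: str | None = None) -> "Recording":
        prov = self.provenance + ((step,) if step else ())
        return replace(self, samples=samples, fs=self.fs if fs is None else fs,
                       provenance=prov)


@dataclass
class EpochedRecording:
    """Non-overlapping fixed-length windows cut from one recording.

    ``epochs`` has shape ``(n_epochs, n_channels, w * fs)``; the trailing
    partial window of the source recording is discarded.
    """

    epochs: np.ndarray
    w: float
    fs: float
    channel_names: tuple[str, ...]
    subject_id: str = ""
    trial_id: str = ""
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x time)")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        expected = int(round(self.w * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} != w*fs = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]
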