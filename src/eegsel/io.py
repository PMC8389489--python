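"""Dataset directories, feature-tensor serialization, and EDF interop.

A synthetic dataset lives as one directory per subject (``s000/``,
``s001/``, ...) holding one channel-major ``.npy`` array per trial plus
a ``subject.json`` sidecar (fs, channel names, EOG channels, per-trial
ratings); dataset-level ground truth sits in ``dataset.json``.  EDF
reading goes through MNE; a minimal EDF writer (16-bit, continuous,
1-second records) is provided for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTensor
from .recording import Recording
from .synth import GroundTruth

__all__ = [
    "save_dataset", "load_dataset", "read_recording",
    "save_features", "load_features", "features_to_long_csv",
    "write_edf",
]


# ---------------------------------------------------------------------------
# synthetic dataset directories

def save_dataset(recordings: list[Recording], truth: GroundTruth | None,
                 path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[Recording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    for sid, recs in by_subject.items():
        sdir = path / sid
        sdir.mkdir(exist_ok=True)
        meta = dict(
            subject_id=sid, fs=recs[0].fs,
            channel_names=list(recs[0].channel_names),
            eog_channels=list(recs[0].eog_channels),
            trials={},
        )
        for rec in recs:
            np.save(sdir / f"{rec.trial_id}.npy", rec.samples.astype(np.float32))
            meta["trials"][rec.trial_id] = {}
        if truth is not None:
            sub = truth.labels[truth.labels.subject_id == sid]
            for row in sub.itertuples():
                meta["trials"][row.trial_id] = dict(
                    valence_rating=float(row.valence_rating),
                    arousal_rating=float(row.arousal_rating),
                    valence_class=int(row.valence_class),
                    arousal_class=int(row.arousal_class),
                )
        (sdir / "subject.json").write_text(json.dumps(meta, indent=1))
    if truth is not None:
        (path / "dataset.json").write_text(json.dumps(dict(
            informative_channels=sorted(truth.informative_channels),
            planted_effect={f"{b}|{c}": v
                            for (b, c), v in truth.planted_effect.items()},
        ), indent=1))
    return path


def load_dataset(path: str | Path) -> tuple[list[Recording], GroundTruth | None]:
    path = Path(path)
    recordings = []
    rows = []
    for sdir in sorted(p for p in path.iterdir() if p.is_dir()):
        meta = _load_sidecar(sdir)
        for tid in sorted(meta["trials"]):
            recordings.append(_read_trial(sdir, tid, meta))
            info = meta["trials"][tid]
            if info:
                rows.append(dict(subject_id=meta["subject_id"], trial_id=tid, **info))
    truth = None
    truth_file = path / "dataset.json"
    if truth_file.exists() and rows:
        info = json.loads(truth_file.read_text())
        planted = {tuple(k.split("|")): v
                   for k, v in info.get("planted_effect", {}).items()}
        truth = GroundTruth(
            informative_channels=frozenset(info["informative_channels"]),
            labels=pd.DataFrame(rows),
            planted_effect=planted,
        )
    return recordings, truth


def _load_sidecar(sdir: Path) -> dict:
    sidecar = sdir / "subject.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("subject_id", "fs", "channel_names", "trials"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing field {key!r}")
    return meta


def _read_trial(sdir: Path, trial_id: str, meta: dict) -> Recording:
    arr = np.load(sdir / f"{trial_id}.npy")
    return Recording(
        samples=arr.astype(float), fs=float(meta["fs"]),
        channel_names=tuple(meta["channel_names"]),
        eog_channels=tuple(meta.get("eog_channels", [])),
        subject_id=meta["subject_id"], trial_id=trial_id,
    )


def read_recording(path: str | Path, format: str = "synth_dir") -> Recording:
    """Read one trial from a synthetic dataset directory or an EDF file.

    For ``synth_dir``, ``path`` is the trial's ``.npy`` file (the
    ``subject.json`` sidecar must sit beside it).
    """
    path = Path(path)
    if format == "synth_dir":
        meta = _load_sidecar(path.parent)
        return _read_trial(path.parent, path.stem, meta)
    if format == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            samples=raw.get_data(), fs=float(raw.info["sfreq"]),
            channel_names=tuple(raw.ch_names),
        )
    raise ValueError(f"unknown format {format!r}; expected 'synth_dir' or 'edf'")


# ---------------------------------------------------------------------------
# feature tensors

def save_features(ft: FeatureTensor, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "values.npy", ft.values)
    np.save(path / "flags.npy", ft.flags)
    (path / "manifest.json").write_text(json.dumps(dict(
        feature_names=list(ft.feature_names),
        channel_names=list(ft.channel_names),
        fs=ft.fs, w=ft.w,
        band_edges=[list(b) for b in ft.band_edges],
        subject_id=ft.subject_id, trial_id=ft.trial_id,
    ), indent=1))
    return path


def load_features(path: str | Path) -> FeatureTensor:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    return FeatureTensor(
        values=np.load(path / "values.npy"),
        flags=np.load(path / "flags.npy"),
        feature_names=tuple(manifest["feature_names"]),
        channel_names=tuple(manifest["channel_names"]),
        fs=manifest["fs"], w=manifest["w"],
        band_edges=tuple((b[0], float(b[1]), float(b[2]))
                         for b in manifest["band_edges"]),
        subject_id=manifest.get("subject_id", ""),
        trial_id=manifest.get("trial_id", ""),
    )


def features_to_long_csv(ft: FeatureTensor, path: str | Path) -> Path:
    """Long-format export: subject, trial, epoch, channel, feature, value."""
    t_idx, c_idx, f_idx = np.meshgrid(
        np.arange(ft.n_epochs), np.arange(ft.n_channels),
        np.arange(ft.n_features), indexing="ij")
    df = pd.DataFrame(dict(
        subject=ft.subject_id, trial=ft.trial_id,
        epoch=t_idx.ravel(),
        channel=np.array(ft.channel_names)[c_idx.ravel()],
        feature=np.array(ft.feature_names)[f_idx.ravel()],
        value=ft.values.ravel(),
    ))
    df.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# EDF export (16-bit, continuous, 1-second data records)

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a basic EDF file (truncates to whole 1-second records)."""
    fs = rec.fs
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    ns = rec.n_channels
    data = rec.samples[:, : n_records * spr]
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax <= pmin
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip((data - pmin[:, None]) * scale[:, None] + dmin,
                      dmin, dmax).astype("<i2")

    header = bytearray()
    header += _pad("0", 8)
    header += _pad(rec.subject_id or "X", 80)
    header += _pad(rec.trial_id or "synthetic", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + ns)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)
    signal_fields = (
        (16, lambda i: rec.channel_names[i]),   # label
        (80, lambda i: ""),                     # transducer
        (8, lambda i: "uV"),                    # physical dimension
        (8, lambda i: f"{pmin[i]:.6g}"),        # physical minimum
        (8, lambda i: f"{pmax[i]:.6g}"),        # physical maximum
        (8, lambda i: str(dmin)),               # digital minimum
        (8, lambda i: str(dmax)),               # digital maximum
        (80, lambda i: ""),                     # prefiltering
        (8, lambda i: str(spr)),                # samples per record
        (32, lambda i: ""),                     # reserved
    )
    for width, fn in signal_fields:
        for i in range(ns):
            header += _pad(fn(i), width)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            for c in range(ns):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())
    return Path(path)
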