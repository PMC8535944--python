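"""Audio and manifest I/O for phonocardiogram (PCG) recordings.

A :class:`PCGRecording` is a mono float signal with a sample rate, an id and a
class label.  Recordings are read from plain RIFF/WAV files (integer PCM is
scaled to [-1, 1] by the full-scale convention 1/2^(bits-1)), resampled with a
polyphase anti-aliased converter and amplitude-normalized so that
max |s| == 1, which is the normalization the segmentation stage assumes.

Dataset manifests are small CSV tables with columns ``split,label,path`` (or
``split,label,count`` for count-only bookkeeping).  :func:`merge_manifest`
reproduces the per-class merge used for the PASCAL-style corpus layout:
normal pools splits A and B (the noisy_normal folder is excluded), murmur
pools A, B and noisy_murmur, extrasystole pools A and B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import DecodeError, EmptySignal, ManifestError, SilentSignal

VALID_LABELS = ("normal", "murmur", "extrasystole", "abnormal", "unlabeled")
VALID_SPLITS = ("A", "B", "noisy_murmur", "noisy_normal")

#: which splits contribute to each merged class total
MERGE_RULES = {
    "normal": ("A", "B"),
    "murmur": ("A", "B", "noisy_murmur"),
    "extrasystole": ("A", "B"),
}


@dataclass
class PCGRecording:
    """A labeled mono heart-sound signal."""

    id: str
    samples: np.ndarray
    sample_rate: int
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("PCGRecording samples must be 1-D (mono)")
        if self.samples.size < 1:
            raise EmptySignal(f"recording {self.id!r} has no samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class ManifestEntry:
    split: str
    label: str
    count: int = 0
    paths: list[str] = field(default_factory=list)


@dataclass
class DatasetManifest:
    """Per-split, per-class bookkeeping of a heart-sound corpus."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.split not in VALID_SPLITS:
                raise ManifestError(f"unknown split {e.split!r}")
            if e.count < 0:
                raise ManifestError(f"negative count for {e.split}/{e.label}")
            if e.paths and e.count != len(e.paths):
                raise ManifestError(
                    f"count {e.count} != number of paths {len(e.paths)} "
                    f"for {e.split}/{e.label}"
                )

    def count(self, split: str, label: str) -> int:
        return sum(e.count for e in self.entries if e.split == split and e.label == label)

    def class_total(self, label: str) -> int:
        return sum(e.count for e in self.entries if e.label == label)


def read_wav(path, *, id: str | None = None, label: str = "unlabeled") -> PCGRecording:
    """Read a WAV file into a mono :class:`PCGRecording`.

    Multichannel audio is averaged to mono; integer PCM is scaled by
    1/2^(bits-1) so full-scale maps to +/-1.
    """
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise DecodeError(f"cannot decode {path}: {exc}") from exc
    if data.size == 0:
        raise EmptySignal(f"{path} contains no audio")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:  # signed PCM
            scale = float(2 ** (info.bits - 1))
            data = data.astype(np.float64) / scale
        else:  # unsigned 8-bit PCM is offset-binary
            scale = float(2 ** (info.bits - 1))
            data = (data.astype(np.float64) - scale) / scale
    else:
        data = data.astype(np.float64)
    if data.ndim > 1:
        data = data.mean(axis=1)
    rec_id = id if id is not None else str(path)
    return PCGRecording(id=rec_id, samples=data, sample_rate=int(rate), label=label)


def write_wav(path, rec: PCGRecording, *, dtype: str = "int16") -> None:
    """Write a recording as PCM WAV (default 16-bit)."""
    if dtype == "float32":
        wavfile.write(path, rec.sample_rate, rec.samples.astype(np.float32))
        return
    info = np.iinfo(dtype)
    scale = float(2 ** (info.bits - 1))
    clipped = np.clip(rec.samples, -1.0, 1.0 - 1.0 / scale)
    wavfile.write(path, rec.sample_rate, np.round(clipped * scale).astype(dtype))


def resample(rec: PCGRecording, target_rate: int, *, allow_upsample: bool = False) -> PCGRecording:
    """Resample to ``target_rate`` Hz with polyphase anti-aliased conversion.

    Duration is preserved within one sample period; the output length is
    round(n * target_rate / sample_rate).  Upsampling emits a warning unless
    ``allow_upsample`` is set, because the pipeline only ever narrows bandwidth.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sample_rate:
        return rec
    if target_rate > rec.sample_rate and not allow_upsample:
        warnings.warn(
            f"upsampling {rec.sample_rate} Hz -> {target_rate} Hz adds no information",
            stacklevel=2,
        )
    g = np.gcd(int(target_rate), int(rec.sample_rate))
    up, down = target_rate // g, rec.sample_rate // g
    out = resample_poly(rec.samples, up, down)
    n_target = int(round(rec.samples.size * target_rate / rec.sample_rate))
    if out.size > n_target:
        out = out[:n_target]
    elif out.size < n_target:
        out = np.pad(out, (0, n_target - out.size))
    return replace(rec, samples=out, sample_rate=int(target_rate))


def normalize_amplitude(rec: PCGRecording) -> PCGRecording:
    """Scale so that max |s| == 1 (the NS = S / max|S| convention)."""
    peak = np.max(np.abs(rec.samples))
    if peak == 0.0:
        raise SilentSignal(f"recording {rec.id!r} is all zeros")
    return replace(rec, samples=rec.samples / peak)


def merge_manifest(raw: DatasetManifest) -> DatasetManifest:
    """Collapse per-split counts into merged per-class totals.

    Normal excludes the noisy_normal split; murmur additionally pools the
    noisy_murmur split; extrasystole pools splits A and B.  The merged manifest
    reports one entry per class under split "A" purely as a carrier (the split
    axis is meaningless after merging).
    """
    merged = []
    for label, splits in MERGE_RULES.items():
        total = sum(raw.count(s, label) for s in splits)
        paths: list[str] = []
        for e in raw.entries:
            if e.label == label and e.split in splits:
                paths.extend(e.paths)
        merged.append(ManifestEntry(split="A", label=label, count=total, paths=paths))
    return DatasetManifest(entries=merged)


def read_manifest(path) -> DatasetManifest:
    """Read a manifest CSV with columns split,label,path or split,label,count."""
    df = pd.read_csv(path, dtype=str)
    cols = set(df.columns)
    if not {"split", "label"} <= cols or not ({"path"} <= cols or {"count"} <= cols):
        raise ManifestError(f"{path}: need columns split,label and path or count")
    entries: list[ManifestEntry] = []
    if "path" in cols:
        for (split, label), grp in df.groupby(["split", "label"], sort=False):
            paths = grp["path"].tolist()
            entries.append(ManifestEntry(split=split, label=label, count=len(paths), paths=paths))
    else:
        for _, row in df.iterrows():
            try:
                n = int(row["count"])
            except (TypeError, ValueError) as exc:
                raise ManifestError(f"bad count {row['count']!r}") from exc
            entries.append(ManifestEntry(split=row["split"], label=row["label"], count=n))
    return DatasetManifest(entries=entries)


def write_manifest(path, manifest: DatasetManifest) -> None:
    rows = []
    for e in manifest.entries:
        if e.paths:
            rows.extend({"split": e.split, "label": e.label, "path": p} for p in e.paths)
        else:
            rows.append({"split": e.split, "label": e.label, "count": e.count})
    pd.DataFrame(rows).to_csv(path, index=False)
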