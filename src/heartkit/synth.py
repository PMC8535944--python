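"""Synthetic phonocardiogram generator with ground-truth beat annotations.

A heart cycle is modeled as a pair of Gaussian-windowed tone bursts: S1 (40 Hz
carrier, 70 ms) at the cycle start and a shorter S2 (60 Hz, 50 ms) at
``systole_fraction`` of the period — textbook first/second heart-sound timing.
Murmur recordings add band-limited noise (120-400 Hz) across the S1->S2
(systolic) interval; extrasystole recordings insert premature beats whose
inter-beat interval shrinks to ``premature_fraction`` of the normal period.
White noise is added at a configurable SNR.  Every sample is reproducible
from the config seed, and each recording ships with exact S1/S2 onset times,
which is what makes the segmentation and selection stages testable without
external corpora.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_io import (
    DatasetManifest,
    ManifestEntry,
    PCGRecording,
    write_manifest,
    write_wav,
)

CLASSES = ("normal", "murmur", "extrasystole")


@dataclass
class SynthConfig:
    duration: float = 10.0  # s
    bpm: float = 75.0
    s1_freq: float = 40.0  # Hz
    s2_freq: float = 60.0
    s1_width: float = 0.070  # s
    s2_width: float = 0.050
    systole_fraction: float = 0.35
    murmur_level: float = 0.4  # relative to S1 peak
    extrasystole_prob: float = 0.25  # per beat
    premature_fraction: float = 0.6
    snr_db: float = 20.0
    sample_rate: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if not 30 <= self.bpm <= 200:
            raise ValueError("bpm must lie in [30, 200]")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        for p in (self.extrasystole_prob, self.systole_fraction, self.premature_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    s1_times: list[float]
    s2_times: list[float]
    beat_labels: list[str]  # normal | extrasystole, per beat
    label: str  # recording class

    def __post_init__(self) -> None:
        for seq in (self.s1_times, self.s2_times):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ValueError("onset times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return len(self.s1_times)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _tone_burst(
    n: int, t0: float, width: float, freq: float, sample_rate: int, amplitude: float = 1.0
) -> np.ndarray:
    """Gaussian-windowed sinusoid of ``width`` seconds starting at ``t0``."""
    t = np.arange(n) / sample_rate
    center = t0 + width / 2.0
    sigma = width / 6.0  # +-3 sigma covers the stated width
    envelope = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    envelope[(t < t0) | (t > t0 + width)] = 0.0
    return amplitude * envelope * np.sin(2.0 * np.pi * freq * (t - t0))


def _systolic_noise(
    n_samples: int, sample_rate: int, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited (120-400 Hz) unit-RMS noise for murmur synthesis."""
    white = rng.standard_normal(n_samples)
    sos = sps.butter(4, [120.0, 400.0], btype="bandpass", fs=sample_rate, output="sos")
    shaped = sps.sosfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def synth_beat(
    cfg: SynthConfig, label: str = "normal", *, period: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """One heart cycle: S1 at phase 0, S2 at systole_fraction * period.

    A ``murmur`` beat adds band-limited noise over the S1->S2 interval.
    Returns the samples and the within-beat ground truth (s1/s2 offsets in s).
    """
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    period = period if period is not None else 60.0 / cfg.bpm
    n = int(round(period * cfg.sample_rate))
    s2_t = cfg.systole_fraction * period
    x = _tone_burst(n, 0.0, cfg.s1_width, cfg.s1_freq, cfg.sample_rate)
    x += _tone_burst(n, s2_t, cfg.s2_width, cfg.s2_freq, cfg.sample_rate, amplitude=0.7)
    if label == "murmur" and cfg.murmur_level > 0:
        noise = _systolic_noise(n, cfg.sample_rate, rng)
        t = np.arange(n) / cfg.sample_rate
        gate = ((t >= cfg.s1_width) & (t <= s2_t)).astype(float)
        x += cfg.murmur_level * gate * noise
    return x, {"s1": 0.0, "s2": s2_t, "period": period}


def synth_recording(
    cfg: SynthConfig, label: str = "normal", *, id: str | None = None
) -> tuple[PCGRecording, GroundTruth]:
    """A full recording of concatenated beats plus additive white noise at snr_db."""
    cfg.validate()
    if label not in CLASSES:
        raise ValueError(f"label must be one of {CLASSES}")
    rng = np.random.default_rng(cfg.seed)
    period = 60.0 / cfg.bpm
    n_total = int(round(cfg.duration * cfg.sample_rate))
    clean = np.zeros(n_total)
    s1_times: list[float] = []
    s2_times: list[float] = []
    beat_labels: list[str] = []
    t = 0.0
    next_is_premature = False
    while t < cfg.duration:
        beat_label = "extrasystole" if next_is_premature else "normal"
        # decide whether the NEXT beat arrives early; that shortens the
        # current cycle (a premature beat follows a short coupling interval)
        next_is_premature = (
            label == "extrasystole" and rng.random() < cfg.extrasystole_prob
        )
        interval = period * cfg.premature_fraction if next_is_premature else period
        beat, gt = synth_beat(cfg, label, period=interval, rng=rng)
        i0 = int(round(t * cfg.sample_rate))
        seg = beat[: max(0, n_total - i0)]
        if seg.size == 0:
            break
        clean[i0 : i0 + seg.size] += seg
        s1_times.append(t)
        s2_n = int(round((t + gt["s2"]) * cfg.sample_rate))
        if s2_n < n_total:
            s2_times.append(t + gt["s2"])
        beat_labels.append(beat_label)
        t += interval
    rms = np.sqrt(np.mean(clean**2))
    noise_rms = rms / (10.0 ** (cfg.snr_db / 20.0))
    samples = clean + noise_rms * rng.standard_normal(n_total)
    rec_id = id or f"synth-{label}-{cfg.seed}"
    rec = PCGRecording(id=rec_id, samples=samples, sample_rate=cfg.sample_rate, label=label)
    gt_all = GroundTruth(
        s1_times=s1_times, s2_times=s2_times, beat_labels=beat_labels, label=label
    )
    return rec, gt_all


def make_dataset(
    n_per_class: int,
    base_cfg: SynthConfig | None = None,
    seed: int = 0,
    *,
    out_dir: str | Path | None = None,
    bpm_range: tuple[float, float] = (60.0, 110.0),
    snr_range: tuple[float, float] = (15.0, 25.0),
) -> tuple[DatasetManifest, list[tuple[PCGRecording, GroundTruth]]]:
    """Balanced corpus over the three classes with jittered bpm and SNR.

    If ``out_dir`` is given, writes per-recording WAV files, a ground-truth
    JSON and a CSV manifest compatible with :mod:`heartkit.signal_io`.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base_cfg = base_cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    recordings: list[tuple[PCGRecording, GroundTruth]] = []
    entries: list[ManifestEntry] = []
    gt_doc: dict[str, dict] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for label in CLASSES:
        paths = []
        for i in range(n_per_class):
            cfg = replace(
                base_cfg,
                bpm=float(rng.uniform(*bpm_range)),
                snr_db=float(rng.uniform(*snr_range)),
                seed=int(rng.integers(2**31 - 1)),
            )
            rec_id = f"{label}-{i:03d}"
            rec, gt = synth_recording(cfg, label, id=rec_id)
            recordings.append((rec, gt))
            gt_doc[rec_id] = json.loads(gt.to_json())
            fname = f"{rec_id}.wav"
            paths.append(fname)
            if out is not None:
                write_wav(out / fname, rec)
        entries.append(
            ManifestEntry(split="A", label=label, count=n_per_class, paths=paths)
        )
    manifest = DatasetManifest(entries=entries)
    if out is not None:
        write_manifest(out / "manifest.csv", manifest)
        (out / "ground_truth.json").write_text(json.dumps(gt_doc, sort_keys=True, indent=1))
    return manifest, recordings
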