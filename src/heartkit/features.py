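"""MFCC features and spectrogram images for heart-cycle segments.

Each segment is framed with a Hamming window (1024 samples by default), each
frame goes through DFT magnitude -> log (floored at a small epsilon) -> a
triangular mel filterbank spanning 0 to Nyquist -> an orthonormal type-II DCT,
and the first ``n_coeffs`` cepstral coefficients are kept.  Note the log is
taken *before* the filterbank smoothing; that ordering is deliberate and is
part of this pipeline's definition of the feature.

The frames x coefficients matrix can be rendered as a fixed-size 480x640 RGB
image (the input shape the image classifiers expect) or summarized into a
per-segment vector of per-coefficient means and standard deviations, which is
what the segment-selection clustering consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image
from scipy.fft import dct, rfft

from .segmentation import HeartCycleSegment

LOG_FLOOR = 1e-10


@dataclass
class MFCCConfig:
    window_len: int = 1024
    hop: int = 512
    n_fft: int = 1024
    n_mels: int = 26
    n_coeffs: int = 13
    window: str = "hamming"

    def validate(self) -> None:
        if self.window_len > self.n_fft:
            raise ValueError("window_len must be <= n_fft")
        if self.n_coeffs > self.n_mels:
            raise ValueError("n_coeffs must be <= n_mels")
        if self.window != "hamming":
            raise ValueError(f"unsupported window {self.window!r}")


@dataclass
class MFCCMatrix:
    coeffs: np.ndarray  # frames x n_coeffs
    segment_id: str


@dataclass
class SpectrogramImage:
    pixels: np.ndarray  # 480 x 640 x 3, uint8
    segment_id: str

    def __post_init__(self) -> None:
        if self.pixels.shape != (480, 640, 3):
            raise ValueError(f"expected 480x640x3, got {self.pixels.shape}")


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """Triangular mel filterbank over the rfft bins, unit-peak filters.

    Returns an (n_mels, n_fft//2 + 1) weight matrix; filter centers are
    equally spaced on the mel scale between 0 Hz and Nyquist.
    """
    n_bins = n_fft // 2 + 1
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2.0), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.arange(n_bins) * sample_rate / n_fft
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        rising = (bin_freqs - lo) / (ctr - lo)
        falling = (hi - bin_freqs) / (hi - ctr)
        fb[m] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def frame_signal(seg: HeartCycleSegment | np.ndarray, cfg: MFCCConfig | None = None) -> np.ndarray:
    """Hamming-windowed frames (n_frames x window_len) of a segment.

    Segments shorter than one window are zero-padded to ``window_len``.
    """
    cfg = cfg or MFCCConfig()
    cfg.validate()
    x = seg.samples if isinstance(seg, HeartCycleSegment) else np.asarray(seg, dtype=np.float64)
    if x.size < cfg.window_len:
        x = np.pad(x, (0, cfg.window_len - x.size))
    n_frames = (x.size - cfg.window_len) // cfg.hop + 1
    idx = np.arange(cfg.window_len)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    return x[idx] * np.hamming(cfg.window_len)[None, :]


def mfcc(
    seg: HeartCycleSegment | np.ndarray,
    cfg: MFCCConfig | None = None,
    *,
    sample_rate: int = 2000,
    segment_id: str | None = None,
) -> MFCCMatrix:
    """Cepstral coefficients of a segment (frames x n_coeffs)."""
    cfg = cfg or MFCCConfig()
    frames = frame_signal(seg, cfg)
    spectrum = np.abs(rfft(frames, n=cfg.n_fft, axis=1))
    log_spectrum = np.log(np.maximum(spectrum, LOG_FLOOR))
    fb = mel_filterbank(cfg.n_mels, cfg.n_fft, sample_rate)
    smoothed = log_spectrum @ fb.T
    cepstra = dct(smoothed, type=2, norm="ortho", axis=1)[:, : cfg.n_coeffs]
    if segment_id is None:
        segment_id = seg.segment_id if isinstance(seg, HeartCycleSegment) else "anon"
    return MFCCMatrix(coeffs=cepstra, segment_id=segment_id)


def render_png(m: MFCCMatrix, *, colormap: str = "viridis") -> SpectrogramImage:
    """Render an MFCC matrix as a deterministic 480x640x3 image.

    Values are linearly mapped min -> 0, max -> 255, run through a fixed
    colormap (time on x, coefficient index on y, coefficient 0 at the bottom)
    and resized with nearest-neighbour interpolation.  A single-valued matrix
    maps to uniform mid-gray.
    """
    c = m.coeffs
    if c.size == 0:
        raise ValueError("empty MFCC matrix")
    lo, hi = float(c.min()), float(c.max())
    if hi == lo:
        pixels = np.full((480, 640, 3), 128, dtype=np.uint8)
        return SpectrogramImage(pixels=pixels, segment_id=m.segment_id)
    scaled = np.round((c - lo) / (hi - lo) * 255.0).astype(np.uint8)
    grid = scaled.T[::-1]  # coefficients on y (0 at bottom), frames on x
    cmap = colormaps[colormap]
    rgb = (cmap(grid / 255.0)[..., :3] * 255.0).round().astype(np.uint8)
    img = Image.fromarray(rgb, mode="RGB").resize((640, 480), Image.NEAREST)
    return SpectrogramImage(pixels=np.asarray(img), segment_id=m.segment_id)


def save_png(img: SpectrogramImage, path) -> None:
    Image.fromarray(img.pixels, mode="RGB").save(path, format="PNG")


def png_bytes(img: SpectrogramImage) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(img.pixels, mode="RGB").save(buf, format="PNG")
    return buf.getvalue()


def summarize_segment_features(m: MFCCMatrix) -> np.ndarray:
    """Per-coefficient mean and (population) std across frames, concatenated."""
    c = m.coeffs
    if c.size == 0:
        raise ValueError("empty MFCC matrix")
    return np.concatenate([c.mean(axis=0), c.std(axis=0)])
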