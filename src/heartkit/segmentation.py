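"""Heart-cycle segmentation.

The segmentation chain turns a denoised, downsampled (2 kHz), amplitude-
normalized recording into single-cardiac-cycle segments:

1. *Low-frequency extraction.*  The signal is decomposed with a Daubechies
   wavelet; every band is thresholded with its own adaptive threshold
   thr = mean(|C|) + f * std(|C|) (coefficients at or above the threshold are
   zeroed, keeping the small-magnitude bulk), and the signal is reconstructed.
2. *Shannon-energy envelope.*  Frame-wise SE = -(1/N) * sum e_j * log e_j with
   e_j the squared sample (0*log 0 := 0), then standardized to zero mean and
   unit standard deviation.  Medium-amplitude transients (S1/S2 lobes)
   dominate this envelope.
3. *Cycle period.*  The unbiased autocorrelation function of the envelope,
   r(tau) = 1/(L-tau) * sum_t x_t x_{t+tau}, peaks at the cardiac period;
   the search is restricted to a physiological lag window (0.4-1.6 s by
   default, i.e. 37-150 bpm).
4. *Cutting.*  S1 onsets are envelope peaks above zero separated by at least
   0.6 period; each onset is refined to the leading edge of its lobe, and a
   segment spans from one onset to one period later (truncated at the next
   onset so segments never overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    ConstantEnvelope,
    EmptyEnvelope,
    EmptyInput,
    NoPeriodicity,
)
from .signal_io import PCGRecording
from .wavelet import WaveletDecomposition, wavedec, waverec


@dataclass
class WaveletConfig:
    """Wavelet family, depth and adaptive-threshold settings.

    ``f`` scales the coefficient spread in thr = mean + f*std.  ``keep_mode``
    'above' (default) is standard hard thresholding: coefficients whose
    (absolute, if ``magnitude``) value is strictly above the threshold are
    kept, the small-magnitude noise floor is zeroed.  'below' inverts the
    rule.
    """

    family_order: int = 6
    levels: int = 5
    f: float = 1.0
    keep_mode: str = "above"  # above | below
    magnitude: bool = True


@dataclass
class EnvelopeSeries:
    """Frame-wise (standardized) Shannon-energy envelope.

    ``sample_rate`` is the rate of the *underlying signal*; the envelope
    itself advances by ``hop`` signal samples per frame.
    """

    values: np.ndarray
    frame_len: int
    hop: int
    sample_rate: int
    standardized: bool = False

    @property
    def frame_rate(self) -> float:
        return self.sample_rate / self.hop


@dataclass
class CycleEstimate:
    """Estimated cardiac-cycle period with a crude confidence score."""

    period_samples: int
    period_seconds: float
    confidence: float


@dataclass
class HeartCycleSegment:
    """One cardiac cycle cut from a recording (half-open sample interval)."""

    recording_id: str
    start: int
    end: int
    samples: np.ndarray
    label: str = "unlabeled"
    segment_id: str = field(default="")

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad segment interval [{self.start}, {self.end})")
        if not self.segment_id:
            self.segment_id = f"{self.recording_id}:{self.start}-{self.end}"


def adaptive_threshold(C: np.ndarray, f: float, *, magnitude: bool = True) -> float:
    """thr = mean(C*) + f * std(C*), with C* = |C| in magnitude mode.

    Uses the population standard deviation.
    """
    C = np.asarray(C, dtype=np.float64)
    if C.size == 0:
        raise EmptyInput("adaptive_threshold needs a nonempty coefficient array")
    stat = np.abs(C) if magnitude else C
    return float(np.mean(stat) + f * np.std(stat))


def threshold_coeffs(C: np.ndarray, thr: float, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Zero coefficients on the wrong side of ``thr`` (strict comparison).

    keep_mode 'below' keeps c_i with compare(c_i) < thr; 'above' keeps
    compare(c_i) > thr; compare is |.| in magnitude mode.
    """
    cfg = cfg or WaveletConfig()
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    C = np.asarray(C, dtype=np.float64)
    cmp = np.abs(C) if cfg.magnitude else C
    keep = cmp < thr if cfg.keep_mode == "below" else cmp > thr
    return np.where(keep, C, 0.0)


def wavelet_low_freq_extract(rec: PCGRecording, cfg: WaveletConfig | None = None) -> PCGRecording:
    """Extract the low-frequency heart sound by per-band adaptive thresholding.

    Every detail band and the approximation band are thresholded with their
    own thr = mean(|C|) + f*std(|C|) before reconstruction; with the default
    keep_mode='above' this suppresses the low-amplitude noise floor and keeps
    the salient S1/S2 (and murmur) structure.
    """
    cfg = cfg or WaveletConfig()
    dec = wavedec(rec.samples, order=cfg.family_order, levels=cfg.levels)
    if np.all(rec.samples == 0):
        return replace(rec, samples=rec.samples.copy())
    new_details = []
    for band in dec.details:
        thr = adaptive_threshold(band, cfg.f, magnitude=cfg.magnitude)
        new_details.append(threshold_coeffs(band, thr, cfg))
    thr_a = adaptive_threshold(dec.approx, cfg.f, magnitude=cfg.magnitude)
    new_approx = threshold_coeffs(dec.approx, thr_a, cfg)
    out = waverec(
        WaveletDecomposition(
            approx=new_approx, details=new_details, lengths=dec.lengths, order=dec.order
        )
    )
    return replace(rec, samples=out)


def shannon_envelope(
    ls: PCGRecording, frame_len: int = 40, hop: int = 20
) -> EnvelopeSeries:
    """Frame-wise Shannon energy SE = -(1/N) sum e_j log e_j, e_j = s_j^2."""
    if frame_len < 2 or hop < 1:
        raise ValueError("need frame_len >= 2 and hop >= 1")
    x = ls.samples
    if x.size < frame_len:
        raise EmptyEnvelope(
            f"signal of {x.size} samples shorter than one frame ({frame_len})"
        )
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    e = x[idx] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = e * np.log(e)
    t[e == 0.0] = 0.0  # 0 * log 0 := 0
    se = -t.mean(axis=1)
    return EnvelopeSeries(
        values=se, frame_len=frame_len, hop=hop, sample_rate=ls.sample_rate
    )


def standardize_envelope(env: EnvelopeSeries) -> EnvelopeSeries:
    """Standardize to zero mean / unit (population) standard deviation."""
    v = env.values
    if v.size < 2:
        raise ConstantEnvelope("need at least two frames to standardize")
    mu, sigma = float(np.mean(v)), float(np.std(v))
    if sigma == 0.0:
        raise ConstantEnvelope("zero-variance envelope")
    return replace(env, values=(v - mu) / sigma, standardized=True)


def estimate_cycle_uacf(
    env: EnvelopeSeries, min_period: float = 0.4, max_period: float = 1.6
) -> CycleEstimate:
    """Cardiac period from the unbiased autocorrelation of the envelope.

    r(tau) = 1/(L-tau) sum_t x_t x_{t+tau}; the period is the lag of the
    highest positive r inside [min_period, max_period] seconds.
    """
    x = env.values
    L = x.size
    frame_rate = env.frame_rate
    lag_min = max(1, int(round(min_period * frame_rate)))
    lag_max = min(L - 2, int(round(max_period * frame_rate)))
    if lag_max < lag_min:
        raise NoPeriodicity(
            f"envelope too short ({L} frames) for periods up to {max_period} s"
        )
    full = np.correlate(x, x, mode="full")[L - 1 :]  # raw lag sums, lag 0..L-1
    counts = L - np.arange(L)
    r = full / counts
    window = r[lag_min : lag_max + 1]
    best = int(np.argmax(window))
    if window[best] <= 0.0:
        raise NoPeriodicity("no positive autocorrelation peak in the lag window")
    lag = lag_min + best
    # Subharmonic disambiguation.  A quasi-periodic envelope peaks at every
    # multiple of the true period, the unbiased normalization favours large
    # lags, and frame-phase quantization can suppress the fundamental peak,
    # so the global maximum often lands on 2x or 3x the period.  Each
    # candidate lag/k is scored by its *harmonic sum* (mean autocorrelation
    # near its first few multiples): the true period scores high at every
    # multiple, while a spurious candidate (e.g. the diastolic S2->S1
    # interval) hits the anti-phase trough at its double and scores low.
    # The smallest candidate within 60% of the best score wins.

    def _harmonic_score(p: int) -> float:
        vals = []
        for m in (1, 2, 3):
            mp = m * p
            if mp > L - 3:
                break
            vals.append(float(r[mp - 2 : mp + 3].max()))
        return float(np.mean(vals))

    candidates = {lag}
    for k in (2, 3, 4):
        cand = int(round(lag / k))
        if cand < lag_min:
            continue
        halo = max(1, cand // 10)
        lo, hi = max(lag_min, cand - halo), min(lag_max, cand + halo)
        local = int(lo + np.argmax(r[lo : hi + 1]))
        if r[local] > 0.0:
            candidates.add(local)
    scores = {c: _harmonic_score(c) for c in candidates}
    best_score = max(scores.values())
    lag = min(c for c, s in scores.items() if s >= 0.6 * best_score)
    confidence = float(np.clip(r[lag] / r[0], 0.0, 1.0)) if r[0] > 0 else 0.0
    period_samples = lag * env.hop
    return CycleEstimate(
        period_samples=period_samples,
        period_seconds=period_samples / env.sample_rate,
        confidence=confidence,
    )


def _s1_anchors(
    values: np.ndarray, period_frames: int, peak_height: float, spacing: int
) -> np.ndarray:
    """Pick one S1 anchor peak per cardiac cycle.

    Both S1 and S2 raise lobes in the Shannon envelope (which emphasizes
    medium amplitudes, so S2 often out-peaks S1).  Systole (S1 -> S2) is
    shorter than diastole (S2 -> next S1), so among the per-lobe peaks the
    ones followed by a *short* gap (< half a period) start a cycle.  If that
    pattern is not recognizable (merged lobes, heavy noise), fall back to the
    highest peak per period.
    """
    fine = max(1, int(round(0.2 * period_frames)))
    all_peaks, _ = find_peaks(values, height=peak_height, distance=fine)
    if all_peaks.size >= 3:
        gaps = np.diff(all_peaks)
        starts_systole = np.append(gaps < 0.5 * period_frames, False)
        anchors = all_peaks[starts_systole]
        if anchors.size >= 2:
            sep = np.diff(anchors)
            # accept when anchors recur roughly once per cycle
            if np.median(sep) >= 0.55 * period_frames:
                return anchors
    coarse, _ = find_peaks(values, height=peak_height, distance=spacing)
    return coarse


def segment_recording(
    rec: PCGRecording,
    env: EnvelopeSeries,
    cyc: CycleEstimate,
    *,
    peak_height: float = 0.0,
    min_spacing_frac: float = 0.6,
    min_tail_frac: float = 0.5,
    s1_halfwidth: float = 0.045,
) -> list[HeartCycleSegment]:
    """Cut the recording at S1 onsets into single-cycle segments.

    Peaks of the standardized envelope above ``peak_height`` mark S1/S2
    lobes; the S1 anchor per cycle is the lobe that starts the short
    (systolic) interval.  The acoustic onset is estimated as the centroid of
    the anchor lobe minus ``s1_halfwidth`` seconds (the envelope lobe is
    centred on the S1 burst, which itself starts about half an S1 duration
    earlier).  Segments span [onset, onset + period) truncated at the next
    onset; a trailing partial cycle shorter than ``min_tail_frac`` * period
    is dropped.
    """
    if not env.standardized:
        env = standardize_envelope(env)
    n = rec.samples.size
    period = cyc.period_samples
    period_frames = max(1, int(round(period / env.hop)))
    spacing = max(1, int(round(min_spacing_frac * period_frames)))
    peaks = _s1_anchors(env.values, period_frames, peak_height, spacing)
    if peaks.size == 0 or n < period:
        warnings.warn(f"recording {rec.id!r}: no complete cycle found", stacklevel=2)
        return []
    v = env.values
    halo = max(2, int(round(0.15 * period_frames)))  # keep S2 out of the lobe
    onsets = []
    for p in peaks:
        a = p
        while a > 0 and p - a < halo and v[a - 1] > 0.0:
            a -= 1
        b = p
        while b < v.size - 1 and b - p < halo and v[b + 1] > 0.0:
            b += 1
        w = v[a : b + 1]
        centroid = float(np.sum(np.arange(a, b + 1) * w) / np.sum(w))
        center = centroid * env.hop + env.frame_len / 2.0  # frame-center dating
        onset = int(round(center - s1_halfwidth * env.sample_rate))
        onsets.append(min(max(0, onset), n - 1))
    onsets = sorted(set(onsets))
    segments: list[HeartCycleSegment] = []
    for i, start in enumerate(onsets):
        end = min(start + period, n)
        if i + 1 < len(onsets):
            end = min(end, onsets[i + 1])
        if end - start < min_tail_frac * period:
            continue
        segments.append(
            HeartCycleSegment(
                recording_id=rec.id,
                start=int(start),
                end=int(end),
                samples=rec.samples[start:end].copy(),
                label=rec.label,
            )
        )
    if not segments:
        warnings.warn(f"recording {rec.id!r}: no complete cycle found", stacklevel=2)
    return segments
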