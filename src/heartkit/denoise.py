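"""IIR denoising of PCG recordings.

Out-of-band noise (baseline wander from chest movement below ~25 Hz, hiss and
ambient noise above the murmur band) is removed with a Butterworth filter
applied forward-backward (zero phase) so that S1/S2 transients are not
shifted.  The primary heart sounds live in roughly 25-120 Hz; murmurs carry
energy to several hundred Hz, so the default band-pass keeps 25-600 Hz.
Filtering runs at the native rate before downsampling, which doubles as
anti-alias protection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import FilterSpecError, NumericalError
from .signal_io import PCGRecording


@dataclass
class FilterSpec:
    """Specification of the denoising IIR filter (Butterworth family)."""

    kind: str = "bandpass"  # bandpass | lowpass | highpass
    order: int = 4
    low_cut: float = 25.0
    high_cut: float = 600.0
    zero_phase: bool = True

    def validate(self, sample_rate: int) -> None:
        nyq = sample_rate / 2.0
        if self.kind not in ("bandpass", "lowpass", "highpass"):
            raise FilterSpecError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise FilterSpecError("order must be >= 1")
        if self.kind == "bandpass":
            if not 0 < self.low_cut < self.high_cut:
                raise FilterSpecError("need 0 < low_cut < high_cut")
            if self.high_cut >= nyq:
                raise FilterSpecError(
                    f"high_cut {self.high_cut} Hz >= Nyquist {nyq} Hz at {sample_rate} Hz"
                )
        elif self.kind == "lowpass":
            if not 0 < self.high_cut < nyq:
                raise FilterSpecError("lowpass cutoff must lie in (0, Nyquist)")
        else:
            if not 0 < self.low_cut < nyq:
                raise FilterSpecError("highpass cutoff must lie in (0, Nyquist)")

    def sos(self, sample_rate: int) -> np.ndarray:
        """Second-order-section coefficients for the given rate."""
        self.validate(sample_rate)
        if self.kind == "bandpass":
            wn = [self.low_cut, self.high_cut]
        elif self.kind == "lowpass":
            wn = self.high_cut
        else:
            wn = self.low_cut
        return sps.butter(self.order, wn, btype=self.kind, fs=sample_rate, output="sos")


def iir_denoise(rec: PCGRecording, spec: FilterSpec | None = None) -> PCGRecording:
    """Apply the IIR filter to a recording, preserving length and rate.

    With ``zero_phase`` the filter runs forward and backward (sosfiltfilt), so
    the effective magnitude response is squared and the phase response is zero.
    """
    spec = spec or FilterSpec()
    sos = spec.sos(rec.sample_rate)
    if spec.zero_phase:
        # sosfiltfilt needs a minimum signal length for its edge padding
        padlen = 3 * (2 * sos.shape[0] + 1)
        if rec.samples.size <= padlen:
            raise FilterSpecError(
                f"signal of {rec.samples.size} samples too short for zero-phase "
                f"filtering (needs > {padlen})"
            )
        out = sps.sosfiltfilt(sos, rec.samples)
    else:
        out = sps.sosfilt(sos, rec.samples)
    if not np.all(np.isfinite(out)):
        raise NumericalError("IIR filter produced non-finite output (unstable?)")
    return replace(rec, samples=out)
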