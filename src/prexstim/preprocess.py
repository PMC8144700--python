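"""Cross-system harmonization: re-referencing, filtering, resampling.

Scalp EEG voltages are only defined relative to a reference.  The two
recording dialects supported here differ in both reference and rate: the
1000 Hz system references to the average of the vertex electrodes
(Fz, Cz, Pz), while the 128 Hz training system uses AFz, which sits at the
centroid of Fz, Fp1 and Fp2 and is treated as equivalent to their average.
Because an average reference is a linear combination of the channels,
re-referencing to the training montage removes the original reference
exactly — whatever it was — which is the algebraic basis for applying a
classifier trained on one system to data from another.

Harmonization therefore (1) re-references to the Fz/Fp1/Fp2 average,
(2) optionally removes slow drift with a 0.5 Hz zero-phase high-pass,
(3) low-passes below the target Nyquist with a zero-phase FIR, and
(4) resamples to 128 Hz by rational polyphase filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .eeg_io import Recording
from .errors import MontageError, ParameterError

TARGET_RATE = 128.0


@dataclass(frozen=True)
class ReferenceSpec:
    """A reference montage: a single electrode or an electrode average."""

    kind: str  # "electrode" | "average"
    members: frozenset[str]

    def __post_init__(self):
        if self.kind not in ("electrode", "average"):
            raise ParameterError(f"unknown reference kind {self.kind!r}")
        if not self.members:
            raise ParameterError("reference must name at least one electrode")
        object.__setattr__(self, "members", frozenset(self.members))

    def describe(self) -> str:
        return f"{self.kind}:{','.join(sorted(self.members))}"

    @classmethod
    def average(cls, *labels: str) -> "ReferenceSpec":
        return cls("average", frozenset(labels))


#: Vertex-average reference of the 1000 Hz acquisition system.
REF_BRAINSCOPE = ReferenceSpec.average("Fz", "Cz", "Pz")
#: Training-montage reference (AFz ~ centroid of Fz, Fp1, Fp2).
REF_TARGET = ReferenceSpec.average("Fz", "Fp1", "Fp2")


def rereference(rec: Recording, target: ReferenceSpec = REF_TARGET) -> Recording:
    """Re-reference every channel to the mean of *target*'s members.

    The result is independent of the recording's original reference: any
    common term added to all channels cancels in the subtraction.  The
    operation is idempotent (the new reference's members average to zero).
    """
    try:
        rows = [rec.channel_index(c) for c in sorted(target.members)]
    except MontageError as exc:
        raise MontageError(f"re-reference target unavailable: {exc}") from exc
    ref_signal = rec.samples[rows].mean(axis=0)
    return rec.with_samples(
        rec.samples - ref_signal[None, :],
        reference=target.describe(),
    )


def _fir_lowpass_taps(cutoff: float, rate: float, attenuation_db: float = 60.0):
    """Kaiser-window FIR whose -6 dB point sits mid-transition.

    The transition band spans 0.9*cutoff (passband edge, ripple < 0.1%) to
    1.25*cutoff (stopband edge, >= `attenuation_db` single-pass).
    """
    width = (1.25 - 0.9) * cutoff
    numtaps, beta = signal.kaiserord(attenuation_db, width / (0.5 * rate))
    numtaps |= 1  # odd length -> symmetric, integer group delay
    mid = (0.9 + 1.25) / 2 * cutoff
    return signal.firwin(numtaps, mid, window=("kaiser", beta), fs=rate)


def lowpass_filter(rec: Recording, cutoff: float) -> Recording:
    """Zero-phase FIR low-pass at *cutoff* Hz."""
    if not 0 < cutoff < rec.rate / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist={rec.rate / 2:g}), got {cutoff}"
        )
    taps = _fir_lowpass_taps(cutoff, rec.rate)
    if len(taps) >= rec.n_samples:
        raise ParameterError(
            f"recording too short ({rec.n_samples} samples) for a "
            f"{len(taps)}-tap filter at this cutoff"
        )
    # Odd-length symmetric FIR applied once, centered: exactly zero phase.
    filtered = signal.oaconvolve(
        rec.samples, taps[None, :], mode="same", axes=1
    )
    return rec.with_samples(filtered)


def highpass_filter(rec: Recording, cutoff: float, order: int = 2) -> Recording:
    """Zero-phase Butterworth high-pass (drift removal)."""
    if not 0 < cutoff < rec.rate / 2:
        raise ParameterError(
            f"cutoff must lie in (0, Nyquist={rec.rate / 2:g}), got {cutoff}"
        )
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.rate, output="sos")
    return rec.with_samples(signal.sosfiltfilt(sos, rec.samples, axis=1))


def resample(rec: Recording, target_rate: float = TARGET_RATE) -> Recording:
    """Resample by rational polyphase filtering (anti-aliased).

    For the 1000 -> 128 Hz conversion the ratio is exactly 16/125, so
    there is no cumulative timing drift.  Output length is
    ``round(n * target_rate / rate)``.
    """
    if not (target_rate > 0 and np.isfinite(target_rate)):
        raise ParameterError(f"target rate must be positive, got {target_rate}")
    if target_rate == rec.rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.samples, up, down, axis=1)
    n_out = int(round(rec.n_samples * target_rate / rec.rate))
    out = out[:, :n_out]
    if out.shape[1] < n_out:  # resample_poly may return one sample short
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])), mode="edge")
    return rec.with_samples(out, rate=float(target_rate))


@dataclass(frozen=True)
class HarmonizationConfig:
    """Preprocessing settings mapping any dialect onto the training montage."""

    target_reference: ReferenceSpec = REF_TARGET
    target_rate: float = TARGET_RATE
    highpass_hz: float | None = 0.5
    anti_alias_cutoff_hz: float = 56.0


def harmonize(rec: Recording, config: HarmonizationConfig | None = None) -> Recording:
    """Re-reference, drift-filter, anti-alias and resample a recording."""
    cfg = config or HarmonizationConfig()
    out = rereference(rec, cfg.target_reference)
    if out.rate > cfg.target_rate:
        out = lowpass_filter(out, cfg.anti_alias_cutoff_hz)
        out = resample(out, cfg.target_rate)
    elif out.rate < cfg.target_rate:
        out = resample(out, cfg.target_rate)
    if cfg.highpass_hz:
        # Drift removal after resampling: linear, so order is immaterial
        # for sub-Nyquist content, and it is cheaper at the target rate.
        out = highpass_filter(out, cfg.highpass_hz)
    return out
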