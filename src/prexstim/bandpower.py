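"""Band-power envelopes and protocol-condition averaging.

Each channel is decomposed into four standard frequency bands — theta
(4-7.5 Hz), alpha (8-12 Hz), beta (14-30 Hz) and gamma (31-45 Hz) — by a
fused Fourier band-pass / analytic-signal construction: the discrete
Fourier transform of the whole recording is taken, only the
positive-frequency bins inside the band are retained (doubled, as in the
Hilbert analytic signal), and the inverse transform yields a complex
band signal whose squared magnitude is the instantaneous band power in
microvolts squared.  Band edges are inclusive.

Envelopes are then averaged within each of the eight protocol-condition
intervals; downstream, those means are normalized to the Rest #1 baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft

from .eeg_io import EventList, Recording
from .errors import ParameterError, ProtocolError
from .protocol import CONDITION_BY_NAME, CONDITION_NAMES, PROTOCOL, ProtocolCondition

__all__ = [
    "FrequencyBand", "THETA", "ALPHA", "BETA", "GAMMA", "BANDS",
    "ProtocolCondition", "PROTOCOL",
    "ProtocolSegmentation", "BandPowerEnvelope", "ConditionMeans",
    "band_power_envelope", "segment_protocol", "condition_mean_power",
]


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ParameterError(
                f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi}]"
            )


THETA = FrequencyBand("theta", 4.0, 7.5)
ALPHA = FrequencyBand("alpha", 8.0, 12.0)
BETA = FrequencyBand("beta", 14.0, 30.0)
GAMMA = FrequencyBand("gamma", 31.0, 45.0)

#: The four analysis bands, in canonical order.
BANDS: tuple[FrequencyBand, ...] = (THETA, ALPHA, BETA, GAMMA)
BAND_BY_NAME = {b.name: b for b in BANDS}


@dataclass
class BandPowerEnvelope:
    """Instantaneous band power, channels x bands x time (uV^2)."""

    channels: tuple[str, ...]
    bands: tuple[FrequencyBand, ...]
    rate: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.channels), len(self.bands))
        if self.values.ndim != 3 or self.values.shape[:2] != expected:
            raise ParameterError(
                f"envelope shape {self.values.shape} does not match "
                f"{expected} channels x bands"
            )


@dataclass(frozen=True)
class ProtocolSegmentation:
    """Half-open sample ranges [start, end) for the eight conditions."""

    segments: tuple[tuple[int, int, int], ...]  # (condition id, start, end)

    def __post_init__(self):
        ids = sorted(s[0] for s in self.segments)
        if ids != [c.id for c in PROTOCOL]:
            raise ProtocolError(
                f"segmentation must cover conditions 1..8 exactly once, got {ids}"
            )

    def range_for(self, condition_id: int) -> tuple[int, int]:
        for cid, start, end in self.segments:
            if cid == condition_id:
                return start, end
        raise ProtocolError(f"no segment for condition {condition_id}")


@dataclass
class ConditionMeans:
    """Mean envelope power per channel x band x condition (uV^2)."""

    channels: tuple[str, ...]
    bands: tuple[FrequencyBand, ...]
    values: np.ndarray  # channels x bands x 8, condition axis ordered by id

    condition_names: tuple[str, ...] = CONDITION_NAMES


def analytic_band_signal(
    x: np.ndarray, rate: float, band: FrequencyBand
) -> np.ndarray:
    """Complex analytic signal restricted to *band* (inclusive edges).

    Computed over the full signal length with no windowing; for x(t) =
    A*cos(2*pi*f*t) with f inside the band, |result|^2 ~ A^2 away from the
    edges.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.fftfreq(n, d=1.0 / rate)
    spectrum = fft.fft(x, axis=-1)
    keep = (freqs >= band.lo) & (freqs <= band.hi)  # positive freqs only
    shaped = np.zeros_like(spectrum)
    shaped[..., keep] = 2.0 * spectrum[..., keep]
    return fft.ifft(shaped, axis=-1)


def band_power_envelope(
    rec: Recording, bands: tuple[FrequencyBand, ...] = BANDS
) -> BandPowerEnvelope:
    """Squared-magnitude analytic envelopes for each channel and band."""
    nyquist = rec.rate / 2
    for band in bands:
        if band.hi >= nyquist:
            raise ParameterError(
                f"band {band.name!r} upper edge {band.hi} Hz reaches the "
                f"Nyquist frequency {nyquist:g} Hz"
            )
    n = rec.n_samples
    freqs = np.fft.fftfreq(n, d=1.0 / rec.rate)
    spectrum = fft.fft(rec.samples, axis=-1)  # shared across bands
    values = np.empty((len(rec.channels), len(bands), n))
    for j, band in enumerate(bands):
        keep = (freqs >= band.lo) & (freqs <= band.hi)
        shaped = np.zeros_like(spectrum)
        shaped[..., keep] = 2.0 * spectrum[..., keep]
        z = fft.ifft(shaped, axis=-1)
        values[:, j, :] = z.real**2 + z.imag**2
    return BandPowerEnvelope(
        channels=rec.channels, bands=tuple(bands), rate=rec.rate, values=values
    )


def save_envelope(env: BandPowerEnvelope, path) -> None:
    """Export an envelope for offline inspection (compressed ``.npz``).

    Layout: ``values`` is channels x bands x time (uV^2), with ``channels``
    (labels), ``bands`` (names) and ``rate`` stored alongside.
    """
    np.savez_compressed(
        path,
        values=env.values,
        channels=np.array(env.channels),
        bands=np.array([b.name for b in env.bands]),
        rate=env.rate,
    )


def segment_protocol(
    events: EventList, rate: float, n_samples: int
) -> ProtocolSegmentation:
    """Convert protocol events to half-open sample ranges.

    All eight conditions must occur exactly once.  A warning is emitted if
    an event's duration deviates more than 10% from the condition's nominal
    duration (protocol deviations are common in clinical recordings but
    worth flagging).
    """
    labels = list(events.labels)
    missing = [name for name in CONDITION_NAMES if name not in labels]
    if missing:
        raise ProtocolError(
            f"protocol events missing condition(s): {', '.join(missing)}"
        )
    segments = []
    for ev in events:
        cond = CONDITION_BY_NAME[ev.label]
        if abs(ev.duration - cond.nominal_duration) > 0.1 * cond.nominal_duration:
            warnings.warn(
                f"condition {ev.label!r} lasts {ev.duration:g}s; nominal is "
                f"{cond.nominal_duration:g}s",
                stacklevel=2,
            )
        start = int(round(ev.onset * rate))
        end = int(round((ev.onset + ev.duration) * rate))
        if end > n_samples:
            raise ProtocolError(
                f"condition {ev.label!r} extends to sample {end}, beyond the "
                f"{n_samples}-sample recording"
            )
        if end <= start:
            raise ProtocolError(f"condition {ev.label!r} spans no samples")
        segments.append((cond.id, start, end))
    return ProtocolSegmentation(tuple(segments))


def condition_mean_power(
    env: BandPowerEnvelope, seg: ProtocolSegmentation, edge_trim: float = 0.0
) -> ConditionMeans:
    """Arithmetic mean of the envelope over each condition's samples.

    ``edge_trim`` (seconds) optionally discards that much from each end of
    every segment before averaging; the default keeps all samples.
    """
    n_t = env.values.shape[2]
    trim = int(round(edge_trim * env.rate))
    out = np.empty((len(env.channels), len(env.bands), len(PROTOCOL)))
    for cid, start, end in seg.segments:
        if end > n_t:
            raise ProtocolError("segmentation extends beyond the envelope")
        lo, hi = start + trim, end - trim
        if hi <= lo:
            raise ProtocolError(
                f"condition {cid} is empty after trimming {edge_trim:g}s edges"
            )
        out[:, :, cid - 1] = env.values[:, :, lo:hi].mean(axis=2)
    return ConditionMeans(channels=env.channels, bands=env.bands, values=out)
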