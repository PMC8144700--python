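"""Recording data model and EDF/event I/O.

A :class:`Recording` is the package's in-memory EEG container: a
channels x time matrix in microvolts over the canonical 19-electrode 10-20
montage, with the sampling rate, a reference descriptor, and optional
protocol events.  Recordings are interchanged on disk as 16-bit EDF+ files
(read through MNE, written by the built-in writer) with condition timing
either embedded as EDF+ annotations or supplied as a TSV sidecar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _edf
from .errors import FormatError, InputError, MontageError, OverlapError
from .montage import CHANNELS_1020, is_montage_label, normalize_channel_label
from .protocol import is_condition_label, normalize_condition_label

logger = logging.getLogger(__name__)

#: Columns of the sidecar event table, in order.
EVENT_COLUMNS = ("onset", "duration", "label")


@dataclass(frozen=True)
class Event:
    """One labelled interval: a protocol condition occurrence."""

    label: str
    onset: float  # seconds from recording start
    duration: float  # seconds, > 0

    def __post_init__(self):
        object.__setattr__(self, "label", normalize_condition_label(self.label))
        if not (self.onset >= 0 and np.isfinite(self.onset)):
            raise InputError(f"event onset must be >= 0, got {self.onset}")
        if not (self.duration > 0 and np.isfinite(self.duration)):
            raise InputError(f"event duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


class EventList:
    """Sorted, non-overlapping list of protocol events."""

    def __init__(self, events):
        entries = sorted(events, key=lambda e: e.onset)
        seen: set[str] = set()
        for prev, nxt in zip(entries, entries[1:]):
            if nxt.onset < prev.end - 1e-9:
                raise OverlapError(
                    f"events {prev.label!r} and {nxt.label!r} overlap "
                    f"({prev.onset:g}+{prev.duration:g}s vs onset {nxt.onset:g}s)"
                )
        for ev in entries:
            if ev.label in seen:
                raise OverlapError(f"duplicate protocol condition {ev.label!r}")
            seen.add(ev.label)
        self._entries: tuple[Event, ...] = tuple(entries)

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def __getitem__(self, i):
        return self._entries[i]

    def __eq__(self, other):
        return isinstance(other, EventList) and self._entries == other._entries

    def __repr__(self):
        return f"EventList({list(self._entries)!r})"

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self._entries)

    def get(self, label: str) -> Event:
        label = normalize_condition_label(label)
        for ev in self._entries:
            if ev.label == label:
                return ev
        raise KeyError(label)


@dataclass
class Recording:
    """Multi-channel EEG with montage labels, rate, reference and events.

    ``samples`` is channels x time in microvolts; rows follow ``channels``,
    which are canonical 10-20 labels.  ``reference`` is a free-text
    descriptor, conventionally ``"average:Fz,Fp1,Fp2"`` or
    ``"electrode:AFz"`` (``"ideal"`` for synthetic common-reference data).
    """

    channels: tuple[str, ...]
    rate: float
    samples: np.ndarray
    reference: str = "unknown"
    events: EventList | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = tuple(normalize_channel_label(c) for c in self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise MontageError("duplicate channel labels in recording")
        if not (self.rate > 0 and np.isfinite(self.rate)):
            raise InputError(f"sampling rate must be positive, got {self.rate}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InputError("samples must be a channels x time matrix")
        if self.samples.shape[0] != len(self.channels):
            raise InputError(
                f"samples has {self.samples.shape[0]} rows for "
                f"{len(self.channels)} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InputError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel_index(self, label: str) -> int:
        label = normalize_channel_label(label)
        try:
            return self.channels.index(label)
        except ValueError:
            raise MontageError(f"channel {label!r} not in recording") from None

    def with_samples(self, samples: np.ndarray, **changes) -> "Recording":
        """Copy with new sample matrix (and optional field changes)."""
        return replace(self, samples=samples, **changes)


def read_edf(path, reference: str = "unknown") -> Recording:
    """Read an EDF/EDF+ file into a canonical-montage :class:`Recording`.

    All 19 montage channels must be present (any spelling); extra channels
    are dropped with a warning.  EDF+ annotations whose description matches
    a protocol condition become the recording's events.  The reference
    descriptor is not stored in EDF, so it must be supplied by the caller.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt files
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc

    canonical_to_raw: dict[str, str] = {}
    for name in raw.ch_names:
        if not is_montage_label(name):
            logger.warning("dropping non-montage channel %r from %s", name, path)
            continue
        canon = normalize_channel_label(name)
        if canon in canonical_to_raw:
            raise MontageError(f"duplicate channel {canon!r} in {path}")
        canonical_to_raw[canon] = name

    missing = [c for c in CHANNELS_1020 if c not in canonical_to_raw]
    if missing:
        raise MontageError(
            f"EDF file {path} is missing montage channels: {', '.join(missing)}"
        )

    picks = [canonical_to_raw[c] for c in CHANNELS_1020]
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts

    events = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if is_condition_label(desc) and duration > 0:
            events.append(Event(desc, float(onset), float(duration)))
        elif desc.strip():
            logger.debug("ignoring non-protocol annotation %r", desc)

    return Recording(
        channels=tuple(CHANNELS_1020),
        rate=float(raw.info["sfreq"]),
        samples=data,
        reference=reference,
        events=EventList(events) if events else None,
    )


def write_edf(
    rec: Recording,
    path,
    physical_range: tuple[float, float] | None = None,
) -> None:
    """Write *rec* as 16-bit EDF+C, with events as EDF+ annotations.

    The physical range defaults to symmetric coverage of the signal
    extrema; round-trip error is bounded by one quantization step of the
    declared range.
    """
    if rec.events is not None:
        for ev in rec.events:
            if ev.end > rec.duration + 1e-6:
                raise InputError(
                    f"event {ev.label!r} ends at {ev.end:g}s, beyond the "
                    f"{rec.duration:g}s recording"
                )
    event_rows = (
        [(e.label, e.onset, e.duration) for e in rec.events] if rec.events else None
    )
    _edf.write_edf_file(
        path,
        labels=list(rec.channels),
        samples=rec.samples,
        rate=rec.rate,
        events=event_rows,
        physical_range=physical_range,
    )


def read_events(path) -> EventList:
    """Read a sidecar event table (TSV: onset, duration, label; seconds)."""
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse event table {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"event table {path} lacks column(s): {', '.join(missing)}"
        )
    events = []
    for i, row in table.iterrows():
        try:
            onset = float(row["onset"])
            duration = float(row["duration"])
        except (TypeError, ValueError):
            raise FormatError(
                f"non-numeric onset/duration in row {i} of {path}"
            ) from None
        events.append(Event(str(row["label"]), onset, duration))
    return EventList(events)


def write_events(events: EventList, path) -> None:
    """Write events as the TSV sidecar format."""
    pd.DataFrame(
        [(e.onset, e.duration, e.label) for e in events],
        columns=list(EVENT_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def attach_events(rec: Recording, events: EventList) -> Recording:
    """Return *rec* with *events* attached (sidecar wins over embedded)."""
    if rec.events is not None and rec.events != events:
        logger.warning("sidecar events override embedded EDF+ annotations")
    return replace(rec, events=events)
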