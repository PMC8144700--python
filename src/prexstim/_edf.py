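"""Minimal EDF+C writer (16-bit) with annotation support.

Writes one ordinary signal per channel plus an ``EDF Annotations`` signal
carrying the per-record timestamps and any events as time-stamped
annotation lists (TALs).  Sample values are quantized to the declared
physical range over the full 16-bit digital range, so the round-trip error
is at most one quantization step ``(phys_max - phys_min) / 65535``.

Recordings whose sample count is a whole multiple of the sampling rate are
stored in one-second data records; any other length is stored as a single
data record (valid EDF, though some readers dislike very large records).
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InputError

# Symmetric digital range so that 0 uV is exactly representable for a
# symmetric physical range.
DIG_MIN = -32767
DIG_MAX = 32767


def _ascii(field: str, width: int) -> bytes:
    data = field.encode("ascii")
    if len(data) > width:
        raise InputError(f"EDF header field too long: {field!r} (> {width})")
    return data.ljust(width)


def _fmt_float(x: float, width: int) -> str:
    """Shortest decimal representation of *x* that fits in *width* chars."""
    if x == int(x) and abs(x) < 10 ** (width - 1):
        return str(int(x))
    for prec in range(width, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width and "e" not in s and "E" not in s:
            return s
    raise InputError(f"cannot format {x!r} in {width} EDF header chars")


def _tal(onset: float, duration: float | None, label: str | None) -> bytes:
    text = f"+{_fmt_float(onset, 16)}" if onset >= 0 else _fmt_float(onset, 16)
    out = text.encode("utf-8")
    if duration is not None:
        out += b"\x15" + _fmt_float(duration, 16).encode("utf-8")
    out += b"\x14"
    if label is not None:
        out += label.encode("utf-8") + b"\x14"
    else:
        out += b"\x14"
    return out + b"\x00"


def write_edf_file(
    path,
    labels: list[str],
    samples: np.ndarray,
    rate: float,
    events: list[tuple[str, float, float]] | None = None,
    physical_range: tuple[float, float] | None = None,
) -> None:
    """Write *samples* (channels x time, microvolts) as EDF+C."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] != len(labels):
        raise InputError("samples must be a channels x time matrix")
    if not np.all(np.isfinite(samples)):
        raise InputError("cannot write non-finite samples to EDF")
    n_ch, n_t = samples.shape
    if n_t == 0:
        raise InputError("cannot write an empty recording")

    if physical_range is None:
        extremum = float(np.max(np.abs(samples))) if samples.size else 0.0
        extremum = max(extremum, 1.0)
        pmin, pmax = -extremum, extremum
    else:
        pmin, pmax = map(float, physical_range)
        if not pmin < pmax:
            raise InputError("physical_range must be (min, max) with min < max")
        if samples.size and (samples.min() < pmin or samples.max() > pmax):
            raise InputError("samples exceed the declared physical range")

    spr_int = int(round(rate))
    if abs(rate - spr_int) < 1e-9 and n_t % spr_int == 0:
        record_duration = 1.0
        spr = spr_int
        n_records = n_t // spr
    else:  # single data record covering the whole signal
        record_duration = n_t / rate
        spr = n_t
        n_records = 1

    # Quantize to the shared 16-bit digital range.
    scale = (DIG_MAX - DIG_MIN) / (pmax - pmin)
    digital = np.rint((samples - pmin) * scale + DIG_MIN)
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    # Annotation payloads: record 0 carries the events, every record carries
    # its timestamp TAL.
    events = events or []
    record_tals = []
    for rec_i in range(n_records):
        payload = _tal(rec_i * record_duration, None, None)
        if rec_i == 0:
            for label, onset, duration in events:
                payload += _tal(onset, duration, label)
        record_tals.append(payload)
    ann_bytes = max(len(p) for p in record_tals)
    ann_spr = math.ceil(ann_bytes / 2) + 8  # int16 samples, with slack

    n_signals = n_ch + 1
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2000 X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (n_signals + 1)), 8),
            _ascii("EDF+C", 44),
            _ascii(str(n_records), 8),
            _ascii(_fmt_float(record_duration, 8), 8),
            _ascii(str(n_signals), 4),
        ]
    )

    def signal_fields(values: list[str], width: int) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    ch_labels = [*labels, "EDF Annotations"]
    header += signal_fields(ch_labels, 16)
    header += signal_fields([""] * n_signals, 80)  # transducer
    header += signal_fields(["uV"] * n_ch + [""], 8)  # dimension
    header += signal_fields([_fmt_float(pmin, 8)] * n_ch + [str(DIG_MIN)], 8)
    header += signal_fields([_fmt_float(pmax, 8)] * n_ch + [str(DIG_MAX)], 8)
    header += signal_fields([str(DIG_MIN)] * n_signals, 8)
    header += signal_fields([str(DIG_MAX)] * n_signals, 8)
    header += signal_fields([""] * n_signals, 80)  # prefiltering
    header += signal_fields([str(spr)] * n_ch + [str(ann_spr)], 8)
    header += signal_fields([""] * n_signals, 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_i in range(n_records):
            block = digital[:, rec_i * spr : (rec_i + 1) * spr]
            fh.write(block.tobytes())
            fh.write(record_tals[rec_i].ljust(ann_spr * 2, b"\x00"))


def quantization_step(physical_range: tuple[float, float]) -> float:
    """Worst-case round-trip error for a declared physical range."""
    pmin, pmax = physical_range
    return (pmax - pmin) / (DIG_MAX - DIG_MIN)
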