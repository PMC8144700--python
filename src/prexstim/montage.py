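"""The 19-electrode 10-20 scalp montage.

The montage vocabulary uses the classic T3/T4/T5/T6 temporal labels; the
modern T7/T8/P7/P8 spellings are accepted on input and normalized.  All
channel matrices in the package follow ``CHANNELS_1020`` order so that
arrays from different files are directly comparable.
"""

from __future__ import annotations

from .errors import MontageError

#: Canonical channel order used by every matrix in the package.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "C3", "C4", "Cz", "T3", "T4", "T5", "T6",
    "P3", "P4", "Pz", "O1", "O2",
)

#: Modern-nomenclature synonyms mapped onto the canonical spelling.
_ALIASES = {
    "t7": "T3",
    "t8": "T4",
    "p7": "T5",
    "p8": "T6",
}

_CANONICAL = {name.lower(): name for name in CHANNELS_1020}


def normalize_channel_label(label: str) -> str:
    """Return the canonical 10-20 spelling for *label*.

    Strips common EDF decorations ("EEG " prefix, "-REF"/"-LE" suffixes),
    then resolves case-insensitively against the 19-electrode set and the
    T7/T8/P7/P8 aliases.

    Raises
    ------
    MontageError
        If the label is not one of the 19 montage electrodes.
    """
    name = label.strip()
    low = name.lower()
    if low.startswith("eeg "):
        low = low[4:].strip()
    for suffix in ("-ref", "-le", "-avg"):
        if low.endswith(suffix):
            low = low[: -len(suffix)].strip()
    if low in _CANONICAL:
        return _CANONICAL[low]
    if low in _ALIASES:
        return _ALIASES[low]
    raise MontageError(f"unknown 10-20 channel label: {label!r}")


def is_montage_label(label: str) -> bool:
    """True if *label* normalizes to one of the 19 montage electrodes."""
    try:
        normalize_channel_label(label)
    except MontageError:
        return False
    return True


def channel_index(channels: list[str] | tuple[str, ...], label: str) -> int:
    """Index of canonical *label* within *channels* (already canonical)."""
    try:
        return list(channels).index(label)
    except ValueError:
        raise MontageError(f"channel {label!r} not present in recording") from None
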