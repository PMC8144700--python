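"""The eight-condition activation protocol.

A recording session follows a fixed sequence: two minutes of rest, a brief
eyes opening/closing block, a short rest with eyes closed, intermittent
photic stimulation, hyperventilation, a second eyes opening/closing block,
another short rest, and a final two-minute rest.  Band-power features are
defined per condition, with Rest #1 serving as the normalization baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import VocabularyError


@dataclass(frozen=True)
class ProtocolCondition:
    """One condition of the activation protocol.

    ``metadata`` carries descriptive detail (e.g. the photic flash-train
    schedule) that plays no role in segmentation.
    """

    id: int
    name: str
    nominal_duration: float  # seconds
    metadata: dict = field(default_factory=dict, compare=False)


#: Photic flash trains as (frequency Hz, duration s); metadata only.
PHOTIC_SCHEDULE = (
    (5, 10), (10, 10), (15, 10), (20, 10), (25, 10), (30, 10),
    (25, 5), (20, 5), (15, 5), (10, 5), (5, 5),
)

PROTOCOL: tuple[ProtocolCondition, ...] = (
    ProtocolCondition(1, "Rest1", 120.0),
    ProtocolCondition(2, "EyesOC1", 10.0),
    ProtocolCondition(3, "Rest2", 10.0),
    ProtocolCondition(4, "Photic", 150.0, {"schedule": PHOTIC_SCHEDULE}),
    ProtocolCondition(5, "Hyperventilation", 240.0),
    ProtocolCondition(6, "EyesOC2", 10.0),
    ProtocolCondition(7, "Rest3", 10.0),
    ProtocolCondition(8, "Rest4", 120.0),
)

CONDITION_NAMES: tuple[str, ...] = tuple(c.name for c in PROTOCOL)
CONDITION_BY_NAME = {c.name: c for c in PROTOCOL}
CONDITION_BY_ID = {c.id: c for c in PROTOCOL}

#: Total nominal protocol length in seconds (670 s).
PROTOCOL_DURATION = sum(c.nominal_duration for c in PROTOCOL)

_LABEL_ALIASES = {
    "rest1": "Rest1", "rest_1": "Rest1", "rest #1": "Rest1",
    "eyesoc1": "EyesOC1", "eyesoc_1": "EyesOC1", "eyes_oc_1": "EyesOC1",
    "eyes opening/closing 1": "EyesOC1",
    "rest2": "Rest2", "rest_2": "Rest2", "rest #2": "Rest2",
    "photic": "Photic", "photic stimulation": "Photic",
    "hyperventilation": "Hyperventilation", "hv": "Hyperventilation",
    "eyesoc2": "EyesOC2", "eyesoc_2": "EyesOC2", "eyes_oc_2": "EyesOC2",
    "eyes opening/closing 2": "EyesOC2",
    "rest3": "Rest3", "rest_3": "Rest3", "rest #3": "Rest3",
    "rest4": "Rest4", "rest_4": "Rest4", "rest #4": "Rest4",
}


def normalize_condition_label(label: str) -> str:
    """Canonical condition name for *label* (case-insensitive, aliases ok)."""
    key = label.strip().lower()
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise VocabularyError(f"unknown protocol condition label: {label!r}")


def is_condition_label(label: str) -> bool:
    try:
        normalize_condition_label(label)
    except VocabularyError:
        return False
    return True


def canonical_onsets() -> dict[str, float]:
    """Condition onsets (s) when conditions run back-to-back from t=0."""
    onsets: dict[str, float] = {}
    t = 0.0
    for cond in PROTOCOL:
        onsets[cond.name] = t
        t += cond.nominal_duration
    return onsets
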