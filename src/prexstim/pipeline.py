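"""End-to-end feature extraction: recording in, feature vector out.

Chains harmonization (re-reference, filter, resample), band-power
envelopes, protocol segmentation, baseline normalization and the
eight-feature extraction.  This is the path both real EDF data and
synthetic cohorts flow through.
"""

from __future__ import annotations

import numpy as np

from .bandpower import (
    BANDS,
    band_power_envelope,
    condition_mean_power,
    segment_protocol,
)
from .eeg_io import EventList, Recording
from .errors import ProtocolError
from .features import (
    FEATURE_SET_V1,
    FeatureDef,
    FeatureMatrix,
    extract_features,
    normalize_to_baseline,
)
from .preprocess import HarmonizationConfig, harmonize


def relative_power_of(
    rec: Recording,
    events: EventList | None = None,
    config: HarmonizationConfig | None = None,
):
    """Harmonized relative power (channels x bands x conditions) of *rec*."""
    events = events or rec.events
    if events is None:
        raise ProtocolError("recording has no protocol events")
    out = harmonize(rec, config)
    env = band_power_envelope(out, BANDS)
    seg = segment_protocol(events, out.rate, out.n_samples)
    means = condition_mean_power(env, seg)
    return normalize_to_baseline(means)


def features_of(
    rec: Recording,
    events: EventList | None = None,
    feature_set: tuple[FeatureDef, ...] = FEATURE_SET_V1,
    config: HarmonizationConfig | None = None,
) -> np.ndarray:
    """The feature vector of one recording."""
    rel = relative_power_of(rec, events, config)
    return extract_features(rel, feature_set)


def feature_matrix_of(
    subjects,
    feature_set: tuple[FeatureDef, ...] = FEATURE_SET_V1,
    config: HarmonizationConfig | None = None,
) -> FeatureMatrix:
    """Stack feature vectors for (subject_id, recording[, label]) tuples.

    ``subjects`` yields ``(id, Recording)`` or ``(id, Recording, label)``
    with label ``"responder"``/``"non-responder"``.
    """
    ids, rows, labels = [], [], []
    labelled = None
    for item in subjects:
        sid, rec = item[0], item[1]
        label = item[2] if len(item) > 2 else None
        if labelled is None:
            labelled = label is not None
        elif labelled != (label is not None):
            raise ProtocolError("either all subjects or none must carry labels")
        ids.append(str(sid))
        rows.append(features_of(rec, feature_set=feature_set, config=config))
        if label is not None:
            labels.append(1 if label == "responder" else 0)
    return FeatureMatrix(
        subject_ids=tuple(ids),
        feature_names=tuple(f.name for f in feature_set),
        values=np.array(rows),
        labels=np.array(labels) if labelled else None,
    )
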