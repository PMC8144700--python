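"""Relative power and the eight published predictor features.

Condition-mean band powers are normalized to the Rest #1 baseline, giving
dimensionless *relative power* values: how strongly each channel's band
power reacts to each protocol condition relative to initial rest.  The
classifier then uses eight fixed (electrode group, condition, band)
averages — the discriminative groups identified in the original training
cohort:

==  =====================  =================  =====
#   electrodes             condition          band
==  =====================  =================  =====
1   Fp2, F4, Fz            Eyes open/close    beta
2   Fp2, F4, Fz            Rest #2            beta
3   Fp2, F4, Fz            Rest #2            theta
4   P4, Pz, T6, O2         Eyes open/close    alpha
5   P3, Pz, T5, O1         Hyperventilation   alpha
6   P3, Pz, T5, O1         Hyperventilation   beta
7   C3, Cz, C4             Hyperventilation   gamma
8   F8, T4                 Rest #4            theta
==  =====================  =================  =====

The protocol has two eyes-opening/closing blocks; the first (condition 2)
is used by default, configurable via :func:`make_feature_set`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bandpower import BAND_BY_NAME, ConditionMeans, FrequencyBand
from .errors import DegenerateBaselineError, FormatError, MontageError, ParameterError
from .montage import normalize_channel_label
from .protocol import CONDITION_BY_ID

REST1_ID = 1


@dataclass
class RelativePower:
    """Condition-mean power normalized to Rest #1 (dimensionless).

    ``values`` is channels x bands x 8 conditions; the Rest #1 plane is
    identically 1 by construction.
    """

    channels: tuple[str, ...]
    bands: tuple[FrequencyBand, ...]
    values: np.ndarray

    def cell(self, channel: str, band: str, condition_id: int) -> float:
        ci = self.channels.index(normalize_channel_label(channel))
        bi = [b.name for b in self.bands].index(band)
        return float(self.values[ci, bi, condition_id - 1])


@dataclass(frozen=True)
class FeatureDef:
    """One predictor: mean relative power over an electrode group."""

    name: str
    electrodes: frozenset[str]
    condition_id: int
    band: str  # band name, resolved against the standard four

    def __post_init__(self):
        object.__setattr__(
            self,
            "electrodes",
            frozenset(normalize_channel_label(e) for e in self.electrodes),
        )
        if not self.electrodes:
            raise ParameterError(f"feature {self.name!r} has no electrodes")
        if self.condition_id == REST1_ID:
            raise ParameterError(
                f"feature {self.name!r} may not use the Rest #1 baseline condition"
            )
        if self.condition_id not in CONDITION_BY_ID:
            raise ParameterError(
                f"feature {self.name!r}: unknown condition id {self.condition_id}"
            )
        if self.band not in BAND_BY_NAME:
            raise ParameterError(f"feature {self.name!r}: unknown band {self.band!r}")


_RF = ("Fp2", "F4", "Fz")
_RPQ = ("P4", "Pz", "T6", "O2")
_LPQ = ("P3", "Pz", "T5", "O1")
_CENTRAL = ("C3", "Cz", "C4")
_RAT = ("F8", "T4")


def make_feature_set(eyes_condition: int = 2) -> tuple[FeatureDef, ...]:
    """The eight published features, with a configurable eyes-O/C block.

    ``eyes_condition`` selects which eyes-opening/closing occurrence
    (condition 2 or 6) features 1 and 4 read from.
    """
    if eyes_condition not in (2, 6):
        raise ParameterError("eyes_condition must be 2 or 6")
    e = eyes_condition
    return (
        FeatureDef("rf_eyesoc_beta", frozenset(_RF), e, "beta"),
        FeatureDef("rf_rest2_beta", frozenset(_RF), 3, "beta"),
        FeatureDef("rf_rest2_theta", frozenset(_RF), 3, "theta"),
        FeatureDef("rpq_eyesoc_alpha", frozenset(_RPQ), e, "alpha"),
        FeatureDef("lpq_hv_alpha", frozenset(_LPQ), 5, "alpha"),
        FeatureDef("lpq_hv_beta", frozenset(_LPQ), 5, "beta"),
        FeatureDef("c_hv_gamma", frozenset(_CENTRAL), 5, "gamma"),
        FeatureDef("rat_rest4_theta", frozenset(_RAT), 8, "theta"),
    )


#: Canonical published feature set (first eyes-O/C occurrence).
FEATURE_SET_V1: tuple[FeatureDef, ...] = make_feature_set(eyes_condition=2)

FEATURE_NAMES_V1: tuple[str, ...] = tuple(f.name for f in FEATURE_SET_V1)

#: Reconstructed candidate-region atlas for re-running feature selection.
#: The atlas the original selection searched over is not published; these
#: ten anatomical groups (the five appearing in the published features
#: plus their standard contralateral/complementary counterparts) are a
#: plausible reconstruction, not the original.
REGION_ATLAS: dict[str, frozenset[str]] = {
    "rf": frozenset(_RF),
    "lf": frozenset({"Fp1", "F3", "Fz"}),
    "rat": frozenset(_RAT),
    "lat": frozenset({"F7", "T3"}),
    "central": frozenset(_CENTRAL),
    "rpq": frozenset(_RPQ),
    "lpq": frozenset(_LPQ),
    "rt": frozenset({"T4", "T6"}),
    "lt": frozenset({"T3", "T5"}),
    "occipital": frozenset({"O1", "O2"}),
}


def candidate_feature_defs(
    regions: dict[str, frozenset[str]] | None = None,
    condition_ids: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma"),
) -> tuple[FeatureDef, ...]:
    """Candidate (region x condition x band) features for selection runs.

    With the default atlas this yields 280 candidates over which
    stepwise-LOO selection can be re-run on new cohorts.
    """
    regions = REGION_ATLAS if regions is None else regions
    return tuple(
        FeatureDef(f"{rname}_c{cid}_{band}", electrodes, cid, band)
        for rname, electrodes in regions.items()
        for cid in condition_ids
        for band in bands
    )


def normalize_to_baseline(means: ConditionMeans) -> RelativePower:
    """Divide every condition mean by the Rest #1 mean of its cell."""
    baseline = means.values[:, :, REST1_ID - 1]
    bad = ~(baseline > 0)
    if np.any(bad):
        ci, bi = np.argwhere(bad)[0]
        raise DegenerateBaselineError(
            f"non-positive Rest #1 baseline for channel "
            f"{means.channels[ci]!r}, band {means.bands[bi].name!r}"
        )
    values = means.values / baseline[:, :, None]
    values[:, :, REST1_ID - 1] = 1.0  # exact, not up-to-rounding
    return RelativePower(channels=means.channels, bands=means.bands, values=values)


def extract_features(
    rel: RelativePower, defs: tuple[FeatureDef, ...] = FEATURE_SET_V1
) -> np.ndarray:
    """Feature vector: per definition, the unweighted electrode-group mean."""
    out = np.empty(len(defs))
    band_names = [b.name for b in rel.bands]
    for j, fd in enumerate(defs):
        try:
            rows = [rel.channels.index(e) for e in sorted(fd.electrodes)]
        except ValueError:
            missing = sorted(fd.electrodes - set(rel.channels))
            raise MontageError(
                f"feature {fd.name!r} needs missing electrode(s): {missing}"
            ) from None
        bi = band_names.index(fd.band)
        out[j] = rel.values[rows, bi, fd.condition_id - 1].mean()
    return out


@dataclass
class FeatureMatrix:
    """Subjects x features table with optional binary labels.

    ``labels`` uses 1 for responders (the positive class), 0 for
    non-responders, or ``None`` in prediction-only mode.
    """

    subject_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # n_subjects x n_features
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ParameterError("feature matrix shape mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.subject_ids),):
                raise ParameterError("labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values, columns=list(self.feature_names),
            index=pd.Index(self.subject_ids, name="subject_id"),
        )
        if self.labels is not None:
            frame["label"] = np.where(self.labels == 1, "responder", "non-responder")
        return frame


LABEL_CODES = {"responder": 1, "non-responder": 0, "1": 1, "0": 0}


def write_feature_table(matrix: FeatureMatrix, path) -> None:
    """Write a lossless TSV (subject_id, features..., optional label)."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path) -> FeatureMatrix:
    """Read the TSV produced by :func:`write_feature_table`."""
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype={"subject_id": str},
            float_precision="round_trip",
        )
    except Exception as exc:
        raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
    if "subject_id" not in frame.columns:
        raise FormatError(f"feature table {path} lacks a subject_id column")
    labels = None
    if "label" in frame.columns:
        try:
            labels = np.array(
                [LABEL_CODES[str(v).strip().lower()] for v in frame["label"]]
            )
        except KeyError as exc:
            raise FormatError(
                f"unknown label value {exc.args[0]!r} in {path}"
            ) from None
    feature_cols = [c for c in frame.columns if c not in ("subject_id", "label")]
    values = np.empty((len(frame), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise FormatError(
                f"non-numeric value in {path}, row {row}, column {col!r}"
            )
        values[:, j] = numeric.to_numpy()
    return FeatureMatrix(
        subject_ids=tuple(frame["subject_id"]),
        feature_names=tuple(feature_cols),
        values=values,
        labels=labels,
    )
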