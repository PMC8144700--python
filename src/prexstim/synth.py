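"""Synthetic protocol-structured EEG cohorts with known class effects.

The generator emulates the statistical structure the classifier assumes:
each channel is a sum of four band-limited Gaussian noise carriers (one
per analysis band) whose amplitude is modulated per protocol condition,
plus a pink (1/f) background floor.  Condition modulation has two parts —
a physiological component shared by everyone (alpha suppression while the
eyes are open, theta/beta increase under hyperventilation) and a
class-dependent *reactivity* multiplier applied to the (electrode group,
condition, band) cells of the predictor features, which is what makes
responders and non-responders separable.

Subjects are rendered against an ideal common reference at a 1000 Hz
source rate and then transformed into a recording dialect:

* ``brainscope_like`` — 1000 Hz, vertex-average reference (Fz, Cz, Pz);
* ``truscan_like`` — 128 Hz, AFz-like reference (Fz, Fp1, Fp2 average).

Because both dialects are linear transforms of the same rendered sources,
they provide the ground truth for the cross-system invariance property.
For pure cohort simulations (no dialect comparison) the source may be
rendered directly at 128 Hz — all carriers live below 45 Hz — which is
substantially cheaper.

Amplitude model closed form: a feature cell with condition modulation m
and class reactivity g has expected relative power (m*g / m_rest)^2,
since envelope power scales with the squared carrier amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import fft

from .bandpower import BANDS, BAND_BY_NAME, FrequencyBand
from .eeg_io import Event, EventList, Recording, write_edf, write_events
from .errors import ConfigError
from .features import FEATURE_SET_V1, FeatureDef
from .montage import CHANNELS_1020
from .preprocess import (
    REF_BRAINSCOPE,
    REF_TARGET,
    ReferenceSpec,
    lowpass_filter,
    rereference,
    resample,
)
from .protocol import PROTOCOL, canonical_onsets

RESPONDER = "responder"
NONRESPONDER = "non-responder"


@dataclass(frozen=True)
class DialectSpec:
    """A recording system's rate and reference montage."""

    name: str
    rate: float
    reference: ReferenceSpec


DIALECT_BRAINSCOPE = DialectSpec("brainscope_like", 1000.0, REF_BRAINSCOPE)
DIALECT_TRUSCAN = DialectSpec("truscan_like", 128.0, REF_TARGET)
DIALECTS = {d.name: d for d in (DIALECT_BRAINSCOPE, DIALECT_TRUSCAN)}


def default_base_amplitude() -> dict[str, float]:
    """Carrier RMS amplitude per band, microvolts (typical adult scalp EEG)."""
    return {"theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 2.0}


def default_condition_modulation() -> dict[tuple[str, int], float]:
    """Physiological modulation m(band, condition id); unlisted cells are 1.

    Alpha is suppressed during the eyes-opening/closing blocks; theta and
    beta rise during hyperventilation (EEG slowing/activation).
    """
    return {
        ("alpha", 2): 0.6,
        ("alpha", 6): 0.6,
        ("theta", 5): 1.5,
        ("beta", 5): 1.3,
    }


def default_class_reactivity(
    g: float = 1.5, features: tuple[str, ...] | None = None
) -> dict[str, dict[str, float]]:
    """Responder reactivity *g* planted on four of the eight feature cells.

    The four cells span both eyes-O/C and hyperventilation conditions and
    all four bands, leaving the remaining features uninformative.
    """
    if features is None:
        features = (
            "rf_eyesoc_beta", "rpq_eyesoc_alpha", "lpq_hv_beta", "c_hv_gamma",
        )
    return {name: {RESPONDER: g, NONRESPONDER: 1.0} for name in features}


@dataclass
class SynthConfig:
    """Cohort-generation settings.

    Defaults follow the published study conditions: a 35 responder / 25
    non-responder training cohort and the two recording dialects.  The
    pink-noise floor defaults to 10% of the total carrier RMS.
    """

    n_responders: int = 35
    n_nonresponders: int = 25
    base_amplitude: dict[str, float] = field(default_factory=default_base_amplitude)
    condition_modulation: dict[tuple[str, int], float] = field(
        default_factory=default_condition_modulation
    )
    class_reactivity: dict[str, dict[str, float]] = field(
        default_factory=default_class_reactivity
    )
    pink_noise_sd: float | None = None  # microvolts; None -> 10% of carrier RMS
    dialect: DialectSpec = DIALECT_BRAINSCOPE
    source_rate: float = 1000.0
    seed: int = 0
    feature_set: tuple[FeatureDef, ...] = FEATURE_SET_V1

    def __post_init__(self):
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ConfigError("cohort sizes must be nonnegative")
        for band, amp in self.base_amplitude.items():
            if band not in BAND_BY_NAME or not amp > 0:
                raise ConfigError(f"bad base amplitude {band!r}: {amp}")
        for (band, cond), m in self.condition_modulation.items():
            if band not in BAND_BY_NAME or cond not in range(1, 9) or not m > 0:
                raise ConfigError(f"bad condition modulation ({band}, {cond}): {m}")
        names = {f.name for f in self.feature_set}
        for fname, per_class in self.class_reactivity.items():
            if fname not in names:
                raise ConfigError(f"reactivity names unknown feature {fname!r}")
            for label, g in per_class.items():
                if label not in (RESPONDER, NONRESPONDER) or not g > 0:
                    raise ConfigError(f"bad reactivity {fname!r}/{label!r}: {g}")
        if self.source_rate < self.dialect.rate:
            raise ConfigError(
                f"source rate {self.source_rate:g} Hz below the dialect rate "
                f"{self.dialect.rate:g} Hz"
            )

    def pink_sd(self) -> float:
        if self.pink_noise_sd is not None:
            return self.pink_noise_sd
        total = np.sqrt(sum(a**2 for a in self.base_amplitude.values()))
        return 0.1 * float(total)

    def cell_multiplier(self, channel: str, band: str, label: str) -> np.ndarray:
        """Amplitude multiplier per condition (length 8) for one carrier."""
        mult = np.ones(len(PROTOCOL))
        for cond in PROTOCOL:
            m = self.condition_modulation.get((band, cond.id), 1.0)
            g = 1.0
            for fd in self.feature_set:
                if (
                    fd.name in self.class_reactivity
                    and channel in fd.electrodes
                    and fd.band == band
                    and fd.condition_id == cond.id
                ):
                    g *= self.class_reactivity[fd.name][label]
            mult[cond.id - 1] = m * g
        return mult


def protocol_events() -> EventList:
    """The canonical back-to-back 670 s protocol."""
    onsets = canonical_onsets()
    return EventList(
        Event(c.name, onsets[c.name], c.nominal_duration) for c in PROTOCOL
    )


def _condition_index(n: int, rate: float) -> np.ndarray:
    """Condition id (1..8) per sample for the canonical protocol."""
    idx = np.empty(n, dtype=int)
    onsets = canonical_onsets()
    for cond in PROTOCOL:
        start = int(round(onsets[cond.name] * rate))
        end = int(round((onsets[cond.name] + cond.nominal_duration) * rate))
        idx[start:min(end, n)] = cond.id
    return idx


def render_source(cfg: SynthConfig, label: str, seed: int) -> Recording:
    """Render one subject at the ideal common reference and source rate.

    Carriers are drawn band-by-band for all channels at once (frequency-
    domain synthesis); the draw order is part of the generator's contract,
    so identical config + seed gives bit-identical recordings.
    """
    if label not in (RESPONDER, NONRESPONDER):
        raise ConfigError(f"unknown class label {label!r}")
    fs = cfg.source_rate
    n = int(round(sum(c.nominal_duration for c in PROTOCOL) * fs))
    rng = np.random.default_rng(seed)
    cond_idx = _condition_index(n, fs) - 1  # 0-based condition per sample
    n_ch = len(CHANNELS_1020)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    def spectral_std(spectrum: np.ndarray) -> np.ndarray:
        # Realized time-domain std of irfft(spectrum) by Parseval; the DC
        # bin is zero throughout, the Nyquist bin (n even) counts once.
        power = np.abs(spectrum) ** 2
        total = 2.0 * power[:, 1:].sum(axis=1)
        if n % 2 == 0:
            total -= power[:, -1]
        return np.sqrt(total) / n

    samples = np.zeros((n_ch, n))
    for band in BANDS:
        keep = (freqs >= band.lo) & (freqs <= band.hi)
        k = int(np.sum(keep))
        if k == 0:
            raise ConfigError(
                f"band {band.name!r} contains no Fourier bins at {fs:g} Hz"
            )
        spectrum = np.zeros((n_ch, len(freqs)), dtype=complex)
        spectrum[:, keep] = rng.standard_normal(
            (n_ch, k)
        ) + 1j * rng.standard_normal((n_ch, k))
        spectrum /= spectral_std(spectrum)[:, None]
        carriers = fft.irfft(spectrum, n=n, axis=1)
        mult = np.array(
            [cfg.cell_multiplier(ch, band.name, label) for ch in CHANNELS_1020]
        )  # channels x 8 conditions
        samples += cfg.base_amplitude[band.name] * mult[:, cond_idx] * carriers

    pink_shape = np.zeros(len(freqs))
    pink_shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = (
        rng.standard_normal((n_ch, len(freqs)))
        + 1j * rng.standard_normal((n_ch, len(freqs)))
    ) * pink_shape
    spectrum /= spectral_std(spectrum)[:, None]
    samples += cfg.pink_sd() * fft.irfft(spectrum, n=n, axis=1)

    return Recording(
        channels=tuple(CHANNELS_1020),
        rate=fs,
        samples=samples,
        reference="ideal",
        events=protocol_events(),
        meta={"label": label, "seed": seed, "dialect": "ideal"},
    )


def to_dialect(rec: Recording, dialect: DialectSpec) -> Recording:
    """Transform an ideal-reference rendering into a recording dialect."""
    out = rereference(rec, dialect.reference)
    if out.rate > dialect.rate:
        out = lowpass_filter(out, 56.0)
        out = resample(out, dialect.rate)
    elif out.rate < dialect.rate:
        raise ConfigError(
            f"source rate {out.rate:g} Hz below dialect rate {dialect.rate:g} Hz"
        )
    out.meta = {**out.meta, "dialect": dialect.name}
    return out


def generate_subject(cfg: SynthConfig, label: str, seed: int) -> Recording:
    """Render one subject in the configured dialect; deterministic in *seed*."""
    return to_dialect(render_source(cfg, label, seed), cfg.dialect)


def subject_seed(master_seed: int, index: int) -> int:
    """Reproducible per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               % 2**31)


def iter_cohort(cfg: SynthConfig):
    """Yield (subject_id, label, seed) rows for the configured cohort."""
    index = 0
    for label, count in (
        (RESPONDER, cfg.n_responders),
        (NONRESPONDER, cfg.n_nonresponders),
    ):
        for _ in range(count):
            yield f"sub-{index + 1:03d}", label, subject_seed(cfg.seed, index)
            index += 1


def generate_cohort(cfg: SynthConfig, outdir) -> pd.DataFrame:
    """Write EDF + sidecar events + manifest for the configured cohort.

    Returns the manifest (subject id, file, label, seed, dialect), which is
    also written to ``manifest.tsv``.
    """
    if cfg.n_responders + cfg.n_nonresponders < 1:
        raise ConfigError("cohort must contain at least one subject")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, label, seed in iter_cohort(cfg):
        rec = generate_subject(cfg, label, seed)
        edf_path = outdir / f"{sid}.edf"
        write_edf(rec, edf_path)
        write_events(rec.events, outdir / f"{sid}_events.tsv")
        rows.append(
            {
                "subject_id": sid,
                "file": edf_path.name,
                "label": label,
                "seed": seed,
                "dialect": cfg.dialect.name,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest


def _pink_band_weight(cfg: SynthConfig, band: FrequencyBand) -> float:
    """Fraction of the unit pink-noise variance that falls inside *band*."""
    n = int(round(sum(c.nominal_duration for c in PROTOCOL) * cfg.source_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.source_rate)
    power = np.zeros(len(freqs))
    power[1:] = 1.0 / freqs[1:]
    keep = (freqs >= band.lo) & (freqs <= band.hi)
    return float(power[keep].sum() / power.sum())


def expected_feature_value(
    cfg: SynthConfig,
    feature: FeatureDef,
    label: str,
    reference: ReferenceSpec | None = REF_TARGET,
    include_noise: bool = True,
) -> float:
    """Closed-form expected relative power for one feature.

    Envelope power follows squared carrier amplitude, so at an ideal
    reference (``reference=None``, ``include_noise=False``) each electrode
    contributes ``(m*g / (m_rest*g_rest))^2`` and the feature is the
    electrode mean.  The value the pipeline actually measures includes two
    further second-order terms that this function accounts for by default:

    * *reference mixing* — carriers are independent across channels, so
      subtracting the reference-average signal adds ``1/r^2`` of each
      reference member's in-band power (``r`` = reference size) to every
      channel, and scales a reference member's own contribution by
      ``(1 - 1/r)^2``;
    * the *pink-noise floor* — the in-band share of the 1/f background
      adds a condition-independent offset to every channel's band power.
    """
    band = BAND_BY_NAME[feature.band]
    amp2 = cfg.base_amplitude[feature.band] ** 2
    noise = (
        cfg.pink_sd() ** 2 * _pink_band_weight(cfg, band) if include_noise else 0.0
    )

    def carrier_power(ch: str, cond_idx: int) -> float:
        # Carrier variance (envelope power is 2x this; the 2 cancels in
        # the Rest #1 ratio).
        mult = cfg.cell_multiplier(ch, feature.band, label)
        return amp2 * mult[cond_idx] ** 2 + noise

    members = sorted(reference.members) if reference is not None else []
    r = len(members)

    def referenced_power(ch: str, cond_idx: int) -> float:
        own = carrier_power(ch, cond_idx)
        if r == 0:
            return own
        if ch in members:
            others = sum(
                carrier_power(m, cond_idx) for m in members if m != ch
            ) / r**2
            return (1 - 1 / r) ** 2 * own + others
        return own + sum(carrier_power(m, cond_idx) for m in members) / r**2

    vals = []
    for ch in sorted(feature.electrodes):
        v_cond = referenced_power(ch, feature.condition_id - 1)
        v_rest = referenced_power(ch, 0)
        vals.append(v_cond / v_rest)
    return float(np.mean(vals))


def render_dialect_pair(
    cfg: SynthConfig, label: str, seed: int
) -> tuple[Recording, Recording]:
    """One subject rendered in both dialects from identical sources."""
    source = render_source(cfg, label, seed)
    return (
        to_dialect(source, DIALECT_BRAINSCOPE),
        to_dialect(source, DIALECT_TRUSCAN),
    )
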