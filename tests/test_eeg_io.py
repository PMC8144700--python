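"""Recording model, EDF round-trips and event tables."""

import logging

import numpy as np
import pytest

from prexstim import _edf
from prexstim.eeg_io import (
    Event,
    EventList,
    Recording,
    attach_events,
    read_edf,
    read_events,
    write_edf,
    write_events,
)
from prexstim.errors import (
    FormatError,
    InputError,
    MontageError,
    OverlapError,
    VocabularyError,
)
from prexstim.montage import CHANNELS_1020, normalize_channel_label
from prexstim.synth import protocol_events


class TestRecordingModel:
    def test_channel_labels_normalized(self):
        rec = Recording(("T7", "t8", "P7", "p8"), 128.0, np.zeros((4, 10)))
        assert rec.channels == ("T3", "T4", "T5", "T6")

    def test_duplicate_channels_rejected(self):
        with pytest.raises(MontageError):
            Recording(("Fp1", "fp1"), 128.0, np.zeros((2, 10)))

    def test_nonfinite_samples_rejected(self):
        bad = np.zeros((1, 4))
        bad[0, 2] = np.nan
        with pytest.raises(InputError):
            Recording(("Fp1",), 128.0, bad)

    @pytest.mark.parametrize("label", ["EEG Fz", "fz-REF", "Cz"])
    def test_edf_decorations_stripped(self, label):
        assert normalize_channel_label(label) in CHANNELS_1020


class TestEdfRoundTrip:
    def test_roundtrip_within_quantization(self, random_recording, tmp_path):
        path = tmp_path / "rec.edf"
        write_edf(random_recording, path)
        back = read_edf(path)
        assert back.channels == random_recording.channels
        assert back.rate == random_recording.rate
        extremum = max(1.0, np.max(np.abs(random_recording.samples)))
        step = _edf.quantization_step((-extremum, extremum))
        assert np.max(np.abs(back.samples - random_recording.samples)) <= step

    def test_constant_zero_reads_back_exact(self, tmp_path):
        rec = Recording(tuple(CHANNELS_1020), 128.0, np.zeros((19, 256)))
        path = tmp_path / "zero.edf"
        write_edf(rec, path)
        assert np.all(read_edf(path).samples == 0.0)

    def test_declared_physical_range_bounds_error(self, tmp_path):
        t = np.arange(512) / 128.0
        samples = np.tile(100.0 * np.sin(2 * np.pi * 10 * t), (19, 1))
        rec = Recording(tuple(CHANNELS_1020), 128.0, samples)
        path = tmp_path / "sine.edf"
        write_edf(rec, path, physical_range=(-1000.0, 1000.0))
        err = np.max(np.abs(read_edf(path).samples - samples))
        assert err <= 2000.0 / 65535

    def test_events_roundtrip_via_independent_reader(self, tmp_path):
        # The annotations written by the built-in writer must be readable
        # by MNE, an independent EDF+ implementation.
        rec = Recording(
            tuple(CHANNELS_1020), 128.0, np.zeros((19, 670 * 128)),
            events=protocol_events(),
        )
        path = tmp_path / "events.edf"
        write_edf(rec, path)
        back = read_edf(path)
        assert len(back.events) == 8
        rest1 = back.events.get("Rest1")
        assert rest1.onset == 0.0 and rest1.duration == 120.0
        assert back.events.get("Hyperventilation").onset == 290.0

    def test_channel_order_permutation_is_canonicalized(self, rng, tmp_path):
        samples = rng.standard_normal((19, 256))
        order = rng.permutation(19)
        path = tmp_path / "perm.edf"
        _edf.write_edf_file(
            path, [CHANNELS_1020[i] for i in order], samples[order], 128.0,
            physical_range=(-10, 10),
        )
        back = read_edf(path)
        assert back.channels == tuple(CHANNELS_1020)
        assert np.allclose(back.samples, samples, atol=20 / 65535)

    def test_missing_channel_named_in_error(self, tmp_path):
        labels = [c for c in CHANNELS_1020 if c != "T6"]
        path = tmp_path / "partial.edf"
        _edf.write_edf_file(path, labels, np.zeros((18, 128)), 128.0)
        with pytest.raises(MontageError, match="T6"):
            read_edf(path)

    def test_extra_channel_dropped_with_warning(self, tmp_path, caplog):
        labels = list(CHANNELS_1020) + ["ECG"]
        path = tmp_path / "extra.edf"
        _edf.write_edf_file(path, labels, np.zeros((20, 128)), 128.0)
        with caplog.at_level(logging.WARNING, logger="prexstim.eeg_io"):
            back = read_edf(path)
        assert len(back.channels) == 19
        assert any("ECG" in m for m in caplog.messages)

    def test_nonfinite_write_rejected(self, tmp_path):
        with pytest.raises(InputError):
            _edf.write_edf_file(
                tmp_path / "bad.edf", ["Fp1"], np.full((1, 8), np.inf), 8.0
            )

    def test_corrupt_file_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.edf"
        path.write_bytes(b"this is not an EDF file")
        with pytest.raises(FormatError):
            read_edf(path)


class TestEventTables:
    def test_sidecar_roundtrip_and_sorting(self, tmp_path):
        events = protocol_events()
        path = tmp_path / "events.tsv"
        write_events(events, path)
        assert read_events(path) == events
        # rows out of order come back sorted
        lines = path.read_text().splitlines()
        shuffled = [lines[0]] + lines[1:][::-1]
        path.write_text("\n".join(shuffled) + "\n")
        assert read_events(path).labels == events.labels

    def test_duplicate_condition_rejected(self):
        with pytest.raises(OverlapError):
            EventList([Event("Rest1", 0, 120), Event("Rest1", 200, 120)])

    def test_overlap_rejected(self):
        with pytest.raises(OverlapError):
            EventList([Event("Rest1", 0, 120), Event("EyesOC1", 100, 10)])

    def test_unknown_label_rejected(self):
        with pytest.raises(VocabularyError):
            Event("Nap", 0, 10)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("onset\tlabel\n0\tRest1\n")
        with pytest.raises(FormatError):
            read_events(path)

    def test_sidecar_overrides_embedded(self, random_recording, caplog):
        embedded = EventList([Event("Rest1", 0, 1)])
        sidecar = EventList([Event("Rest1", 0, 2)])
        rec = random_recording.with_samples(
            random_recording.samples, events=embedded
        )
        with caplog.at_level(logging.WARNING, logger="prexstim.eeg_io"):
            out = attach_events(rec, sidecar)
        assert out.events == sidecar
        assert caplog.messages
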