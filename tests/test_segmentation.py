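import numpy as np
import pytest

from fpevent import (RawRecording, SegmentationSpec, SubjectBlockID,
                     add_derived_variable, baseline_correct, extract_events,
                     segment_recording)
from fpevent.segmentation import UNKNOWN_LABEL


def make_recording(codes, channels=None, fs=1000.0):
    codes = np.asarray(codes)
    n = len(codes)
    if channels is None:
        channels = {"Mx": np.arange(n, dtype=float)}
    return RawRecording(id=SubjectBlockID(1, 1), sampling_rate=fs,
                        time=np.arange(n) / fs * 1000.0,
                        channels=channels, trigger_codes=codes)


def simple_trial_codes():
    """Two trials: lead-in, then 128 -> stim -> resp -> ITI each."""
    return np.concatenate([
        np.full(50, 0),
        np.full(216, 128), np.full(300, 1), np.full(150, 32), np.full(400, 0),
        np.full(217, 128), np.full(280, 4), np.full(150, 64), np.full(300, 0),
    ])


class TestSegmentRecording:
    def segment(self, codes, spec=None, **rec_kw):
        rec = make_recording(codes, **rec_kw)
        events = extract_events(rec.trigger_codes, rec.sampling_rate)
        return rec, segment_recording(rec, events, spec or SegmentationSpec())

    def test_boundaries_at_start_trigger_onsets(self):
        rec, segs = self.segment(simple_trial_codes())
        assert [s.start_sample for s in segs] == [50, 50 + 216 + 300 + 150 + 400]
        assert segs[0].n_samples == 216 + 300 + 150 + 400
        # final trial runs to the end of the recording
        assert segs[1].start_sample + segs[1].n_samples == rec.n_samples

    def test_pre_trigger_prefix_belongs_to_no_trial(self):
        _, segs = self.segment(simple_trial_codes())
        assert segs[0].start_sample == 50

    def test_partition_reconstructs_sample_range(self):
        rec, segs = self.segment(simple_trial_codes())
        covered = []
        for s in segs:
            covered.extend(range(s.start_sample, s.start_sample + s.n_samples))
        assert covered == list(range(segs[0].start_sample, rec.n_samples))

    def test_trial_numbering_and_conditions(self):
        _, segs = self.segment(simple_trial_codes())
        assert [s.trial for s in segs] == [1, 2]
        assert segs[0].conditions == {"stimulus": "left-A",
                                      "correctness": "correct"}
        assert segs[1].conditions == {"stimulus": "right-A",
                                      "correctness": "incorrect"}

    def test_missing_response_flags_incomplete_only_that_trial(self):
        codes = simple_trial_codes()
        codes[(codes == 32)] = 1  # first trial's response never arrives
        _, segs = self.segment(codes)
        assert [s.complete for s in segs] == [False, True]

    def test_unknown_code_maps_to_explicit_unknown_label(self):
        spec = SegmentationSpec(condition_maps={"stimulus": {2: "two"}})
        _, segs = self.segment(simple_trial_codes(), spec)
        assert segs[0].conditions["stimulus"] == UNKNOWN_LABEL

    def test_no_start_trigger_is_an_error(self):
        with pytest.raises(ValueError, match="start-trigger"):
            self.segment(np.full(100, 0))

    def test_trial_count_mismatch_warns_and_proceeds(self):
        spec = SegmentationSpec(n_trials_expected=5)
        with pytest.warns(UserWarning, match="expected 5.*found 2"):
            _, segs = self.segment(simple_trial_codes(), spec)
        assert len(segs) == 2

    def test_event_onsets_relative_to_trial_start(self):
        _, segs = self.segment(simple_trial_codes())
        assert segs[0].events[0].code == 128
        assert segs[0].events[0].onset_sample == 0
        stim = segs[0].find_event([1, 2, 4, 8])
        assert stim.onset_sample == 216

    def test_synthetic_corpus_boundaries_match_schedule(self, small_corpus,
                                                        seg_spec):
        recordings, schedule = small_corpus
        for rec in recordings:
            sched = schedule[schedule["block"] == rec.id.block]
            events = extract_events(rec.trigger_codes, rec.sampling_rate)
            segs = segment_recording(rec, events, seg_spec)
            assert [s.start_sample for s in segs] == \
                sched["fixation_onset"].tolist()
            assert all(s.complete for s in segs)


class TestBaselineCorrect:
    fs = 1000.0

    def one_trial(self, channel):
        codes = np.concatenate([np.full(216, 128), np.full(300, 1),
                                np.full(150, 32), np.full(334, 0)])
        rec = make_recording(codes, channels={"Mx": np.asarray(channel,
                                                               dtype=float)})
        events = extract_events(rec.trigger_codes, rec.sampling_rate)
        return segment_recording(rec, events, SegmentationSpec())[0]

    def test_constant_channel_becomes_zero(self):
        seg = self.one_trial(np.full(1000, 5.5))
        out = baseline_correct(seg, SegmentationSpec(), ["Mx"])
        np.testing.assert_allclose(out.channels["Mx"], 0.0, atol=1e-12)
        assert out.baseline_applied

    def test_interval_mean_is_zero_and_spans_216_samples(self, rng):
        seg = self.one_trial(rng.normal(size=1000))
        out = baseline_correct(seg, SegmentationSpec(), ["Mx"])
        scale = np.abs(seg.channels["Mx"]).max()
        assert abs(out.channels["Mx"][:216].mean()) <= 1e-9 * scale
        # the subtracted constant is the mean of exactly samples 0..215
        shift = seg.channels["Mx"] - out.channels["Mx"]
        np.testing.assert_allclose(shift, seg.channels["Mx"][:216].mean())

    def test_idempotence(self, rng):
        seg = self.one_trial(rng.normal(size=1000))
        once = baseline_correct(seg, SegmentationSpec(), ["Mx"])
        twice = baseline_correct(once, SegmentationSpec(), ["Mx"])
        np.testing.assert_allclose(once.channels["Mx"], twice.channels["Mx"],
                                   atol=1e-12)

    def test_missing_baseline_trigger_warns_and_flags(self, rng):
        seg = self.one_trial(rng.normal(size=1000))
        spec = SegmentationSpec(baseline_trigger=99)
        with pytest.warns(UserWarning, match="baseline trigger"):
            out = baseline_correct(seg, spec, ["Mx"])
        assert out.baseline_missing and not out.baseline_applied
        np.testing.assert_array_equal(out.channels["Mx"], seg.channels["Mx"])

    def test_interval_exceeding_trial_truncates_with_warning(self, rng):
        seg = self.one_trial(rng.normal(size=1000))
        spec = SegmentationSpec(baseline_interval_ms=(0.0, 5000.0))
        with pytest.warns(UserWarning, match="truncat"):
            out = baseline_correct(seg, spec, ["Mx"])
        assert abs(out.channels["Mx"].mean()) < 1e-9

    def test_unknown_channel_rejected(self, rng):
        seg = self.one_trial(rng.normal(size=1000))
        with pytest.raises(KeyError):
            baseline_correct(seg, SegmentationSpec(), ["Qz"])


class TestAddDerivedVariable:
    def segments(self, rng):
        codes = np.concatenate([np.full(216, 128), np.full(300, 1),
                                np.full(150, 32), np.full(334, 0)])
        channels = {"Mx": rng.normal(size=1000),
                    "My": rng.normal(size=1000),
                    "Fz": np.full(1000, 4.0)}
        rec = make_recording(codes, channels=channels)
        events = extract_events(rec.trigger_codes, rec.sampling_rate)
        return segment_recording(rec, events, SegmentationSpec())

    def test_copy_and_difference_transforms(self, rng):
        segs = self.segments(rng)
        segs = add_derived_variable(segs, "MxCopy", lambda Mx: Mx)
        segs = add_derived_variable(segs, "Mdiff", lambda Mx, My: Mx - My)
        s = segs[0]
        np.testing.assert_array_equal(s.channels["MxCopy"], s.channels["Mx"])
        np.testing.assert_allclose(
            s.channels["Mdiff"], s.channels["Mx"] - s.channels["My"])

    def test_ratio_with_constant_denominator(self, rng):
        segs = add_derived_variable(self.segments(rng), "CoPx",
                                    lambda Mx, Fz: Mx / Fz)
        s = segs[0]
        np.testing.assert_allclose(s.channels["CoPx"],
                                   s.channels["Mx"] / 4.0)

    def test_name_collision_rejected(self, rng):
        with pytest.raises(ValueError, match="already exists"):
            add_derived_variable(self.segments(rng), "Mx", lambda My: My)

    def test_unknown_input_channel_rejected(self, rng):
        with pytest.raises(KeyError):
            add_derived_variable(self.segments(rng), "X", lambda Qz: Qz)
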