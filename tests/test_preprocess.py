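"""Task segmentation, 1-s epoching and artifact rejection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from examcoh.montage import CHANNELS
from examcoh.preprocess import (EpochSet, epoch_segment, override_mask,
                                reject_artifacts, segment_tasks)
from examcoh.recording import Recording

from conftest import white_noise_epochs


def _recording(duration_s, markers, fs=256.0, seed=0):
    r = np.random.default_rng(seed)
    data = r.normal(0.0, 20.0, (14, int(duration_s * fs)))
    return Recording(CHANNELS, fs, data, markers=list(markers))


DEFAULT_MARKERS = [("eyes open", 0.0), ("reading", 180.0),
                   ("answer 1", 360.0), ("answer 2", 1080.0)]


class TestSegmentTasks:
    def test_default_plan_intervals(self):
        rec = _recording(1260, DEFAULT_MARKERS)
        bounds = segment_tasks(rec)
        assert bounds == {"baseline": (0.0, 180.0), "reading": (180.0, 360.0),
                          "answer1": (360.0, 1080.0),
                          "answer2": (1080.0, 1260.0)}

    def test_marker_labels_case_and_space_insensitive(self):
        markers = [("Eyes  Open", 0.0), ("READING", 10.0),
                   ("Answer 1", 20.0), ("answer  2", 30.0)]
        rec = _recording(40, markers)
        assert set(segment_tasks(rec)) == {"baseline", "reading",
                                           "answer1", "answer2"}

    def test_truncated_recording_clips_last_segment(self):
        rec = _recording(1100, DEFAULT_MARKERS)  # ends mid answer-2
        assert segment_tasks(rec)["answer2"] == (1080.0, 1100.0)

    def test_duplicate_marker_rejected(self):
        rec = _recording(1260, DEFAULT_MARKERS + [("reading", 500.0)])
        with pytest.raises(ValueError, match="duplicated"):
            segment_tasks(rec)

    def test_missing_marker_named(self):
        rec = _recording(1260, DEFAULT_MARKERS[:3])
        with pytest.raises(ValueError, match="answer2"):
            segment_tasks(rec)

    def test_out_of_order_markers_rejected(self):
        markers = [("eyes open", 10.0), ("reading", 0.0),
                   ("answer 1", 20.0), ("answer 2", 30.0)]
        with pytest.raises(ValueError, match="order"):
            segment_tasks(_recording(40, markers))


class TestEpochSegment:
    def test_exact_division(self):
        rec = _recording(180, DEFAULT_MARKERS[:1])
        es = epoch_segment(rec, (0.0, 180.0), task="baseline")
        assert es.epochs.shape == (180, 14, 256)
        assert not es.artifact_mask.any()

    def test_tail_dropped(self):
        rec = _recording(181, DEFAULT_MARKERS[:1])
        es = epoch_segment(rec, (0.0, 180.7))
        assert es.n_epochs == 180

    def test_partition_reproduces_signal(self):
        rec = _recording(10, DEFAULT_MARKERS[:1])
        es = epoch_segment(rec, (0.0, 10.0))
        glued = es.epochs.swapaxes(0, 1).reshape(14, -1)
        assert np.array_equal(glued, rec.data[:, :glued.shape[1]])

    def test_short_interval_warns_and_is_empty(self):
        rec = _recording(10, DEFAULT_MARKERS[:1])
        with pytest.warns(UserWarning, match="shorter"):
            es = epoch_segment(rec, (0.0, 0.5))
        assert es.n_epochs == 0

    def test_interval_outside_recording_rejected(self):
        rec = _recording(10, DEFAULT_MARKERS[:1])
        with pytest.raises(ValueError, match="outside"):
            epoch_segment(rec, (5.0, 30.0))


class TestRejectArtifacts:
    def test_transient_masked_clean_kept(self):
        es = white_noise_epochs(20, n_channels=14, sd=10.0, seed=3)
        es.epochs[7, 2, 100:140] += 500.0
        out = reject_artifacts(es, abs_thresh=100.0)
        assert out.artifact_mask[7]
        assert out.artifact_mask.sum() == 1

    def test_flatline_masked(self):
        es = white_noise_epochs(5, n_channels=14, sd=10.0, seed=4)
        es.epochs[2, 5, :] = 42.0  # dead channel: constant offset
        out = reject_artifacts(es)
        assert out.artifact_mask[2]

    def test_thresholds_must_be_positive(self):
        es = white_noise_epochs(3)
        with pytest.raises(ValueError):
            reject_artifacts(es, abs_thresh=0.0)

    @given(scale=st.floats(min_value=0.2, max_value=5.0))
    def test_mask_monotone_in_thresholds(self, scale):
        es = white_noise_epochs(30, n_channels=4, sd=40.0, seed=9)
        loose = reject_artifacts(es, 120.0, 240.0, 0.1)
        strict = reject_artifacts(es, 120.0 / scale if scale > 1 else 120.0,
                                  240.0 / scale if scale > 1 else 240.0, 0.1)
        if scale > 1:  # stricter thresholds never unmask
            assert (strict.artifact_mask | loose.artifact_mask
                    == strict.artifact_mask).all()

    def test_mask_permutation_equivariant(self, rng):
        es = white_noise_epochs(40, n_channels=4, sd=45.0, seed=10)
        perm = rng.permutation(40)
        masked = reject_artifacts(es, 100.0, 200.0, 0.1).artifact_mask
        es_p = EpochSet(task=es.task, epochs=es.epochs[perm],
                        sampling_rate=es.sampling_rate)
        masked_p = reject_artifacts(es_p, 100.0, 200.0, 0.1).artifact_mask
        assert np.array_equal(masked_p, masked[perm])

    def test_override_mask(self):
        es = white_noise_epochs(10)
        auto = reject_artifacts(es)
        out = override_mask(auto, force_reject=(1, 2), force_keep=(3,))
        assert out.artifact_mask[1] and out.artifact_mask[2]
        assert not out.artifact_mask[3]
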