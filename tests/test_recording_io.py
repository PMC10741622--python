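"""Recording container, montage validation and file format round trips."""

import numpy as np
import pytest

from examcoh._xdf import XdfParseError
from examcoh.io import read_recording, write_recording
from examcoh.montage import CHANNELS, N_PAIRS, canonical_pairs, pair_name
from examcoh.recording import Recording, reorder_canonical, validate_montage


@pytest.fixture()
def recording(rng):
    return Recording(
        CHANNELS, 256.0, rng.normal(0.0, 20.0, (14, 256 * 5)),
        markers=[("eyes open", 0.0), ("reading", 1.0),
                 ("answer 1", 2.0), ("answer 2", 4.0)],
        meta={"participant": "p01"})


def test_montage_pair_conventions():
    pairs = canonical_pairs()
    assert len(pairs) == N_PAIRS == 91
    assert len(set(pairs)) == 91
    # pair naming is order independent and follows montage order
    assert pair_name("FC6", "FC5") == pair_name("FC5", "FC6") == "FC5-FC6"
    with pytest.raises(ValueError):
        pair_name("F7", "F7")


def test_validate_montage_clean(recording):
    assert validate_montage(recording) == []


def test_validate_montage_reports_issues(recording):
    rec = recording.copy()
    rec.markers = [m for m in rec.markers if m[0] != "answer 2"]
    rec.data[3, 17] = np.nan
    issues = validate_montage(rec)
    assert any("answer 2" in msg for msg in issues)
    assert any("FC5" in msg and "17" in msg for msg in issues)


def test_validate_montage_flags_unknown_marker(recording):
    rec = recording.copy()
    rec.markers.append(("coffee break", 3.0))
    assert any("coffee break" in msg for msg in validate_montage(rec))


@pytest.mark.parametrize("fmt", ["fixture-csv", "edf", "xdf"])
def test_round_trip(recording, fmt, tmp_path):
    suffix = {"fixture-csv": "csv", "edf": "edf", "xdf": "xdf"}[fmt]
    path = tmp_path / f"rec.{suffix}"
    write_recording(recording, path, format=fmt)
    back = read_recording(path, format=fmt)
    assert back.channel_labels == tuple(CHANNELS)
    assert back.sampling_rate == recording.sampling_rate
    assert [(lab, pytest.approx(on)) for lab, on in back.markers] \
        == list(recording.markers)
    if fmt == "edf":
        # EDF is 16-bit: exact up to one least-significant bit
        pmax = np.ceil(np.abs(recording.data).max())
        lsb = 2 * pmax / 65535
        assert lsb <= 0.51  # finer than the acquisition hardware resolution
        assert np.abs(back.data - recording.data).max() <= lsb
    else:
        assert np.array_equal(back.data, recording.data)


def test_edf_shuffled_channels_reordered(recording, rng, tmp_path):
    perm = rng.permutation(14)
    shuffled = Recording(tuple(np.asarray(CHANNELS)[perm]), 256.0,
                         recording.data[perm], markers=recording.markers)
    write_recording(shuffled, tmp_path / "shuf.edf")
    back = read_recording(tmp_path / "shuf.edf")
    assert back.channel_labels == tuple(CHANNELS)
    pmax = np.ceil(np.abs(recording.data).max())
    assert np.abs(back.channel("F7")
                  - recording.channel("F7")).max() <= 2 * pmax / 65535


def test_edf_header_duration_and_empty_markers(tmp_path, rng):
    rec = Recording(CHANNELS, 256.0, rng.normal(0, 10, (14, 256)), markers=[])
    write_recording(rec, tmp_path / "one.edf")
    head = (tmp_path / "one.edf").read_bytes()[:256]
    n_records = int(head[236:244].decode().strip())
    record_duration = float(head[244:252].decode().strip())
    assert n_records * record_duration == 1.0
    back = read_recording(tmp_path / "one.edf")
    assert back.duration == 1.0 and back.markers == []


def test_edf_warns_when_resolution_too_coarse(tmp_path, rng):
    rec = Recording(CHANNELS, 256.0,
                    rng.normal(0, 30000.0, (14, 256)), markers=[])
    with pytest.warns(UserWarning, match="gain"):
        write_recording(rec, tmp_path / "big.edf")


def test_missing_channel_fails_loudly(recording, tmp_path):
    rec13 = Recording(CHANNELS[:13], 256.0, recording.data[:13], markers=[])
    write_recording(rec13, tmp_path / "r13.csv")
    with pytest.raises(ValueError, match="AF4"):
        read_recording(tmp_path / "r13.csv")


def test_reorder_drops_extra_channels(recording):
    labels = tuple(CHANNELS) + ("EXG1",)
    data = np.vstack([recording.data, np.zeros((1, recording.n_samples))])
    rec = Recording(labels, 256.0, data)
    out = reorder_canonical(rec)
    assert out.channel_labels == tuple(CHANNELS)
    assert out.n_channels == 14


def test_xdf_markers_match_sidecar_onsets(recording, tmp_path):
    write_recording(recording, tmp_path / "rec.xdf")
    back = read_recording(tmp_path / "rec.xdf")
    assert len(back.markers) == 4
    assert [on for _, on in back.markers] == [0.0, 1.0, 2.0, 4.0]


def test_corrupt_xdf_reports_byte_offset(tmp_path):
    path = tmp_path / "bad.xdf"
    path.write_bytes(b"XDF:\x01\x05\x63\x00garbage")
    with pytest.raises(XdfParseError, match="byte offset"):
        read_recording(path, format="xdf")
    path.write_bytes(b"NOPE")
    with pytest.raises(XdfParseError, match="offset 0"):
        read_recording(path, format="xdf")


def test_recording_rejects_bad_shapes():
    with pytest.raises(ValueError, match="2-D"):
        Recording(CHANNELS, 256.0, np.zeros(14))
    with pytest.raises(ValueError, match="labels"):
        Recording(CHANNELS[:3], 256.0, np.zeros((14, 10)))
    with pytest.raises(ValueError, match="sampling_rate"):
        Recording(CHANNELS, 0.0, np.zeros((14, 10)))
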