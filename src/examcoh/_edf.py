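"""Minimal EDF+C writer (16-bit, 1-s data records, annotation channel).

Writes standard-conformant European Data Format files readable by any
EDF+ reader (round-trips through :func:`mne.io.read_raw_edf`).  Scope is
deliberately small: continuous recordings, one sampling rate for all
signals, markers stored as EDF+ time-stamped annotations (TALs).
Amplitude resolution is the physical range over the 16-bit digital
span; callers get a warning (and a gain note in the transducer field)
if that resolution would be coarser than the acquisition hardware's
0.51 µV per least-significant bit.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .recording import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767
#: Reference amplitude resolution of the acquisition hardware (µV/LSB).
REFERENCE_LSB_UV = 0.51


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def _annotation_payload(markers: list[tuple[str, float]], record: int,
                        n_bytes: int) -> bytes:
    """TAL byte block for one data record."""
    tal = f"+{record}\x14\x14\x00".encode("ascii")
    for label, onset in markers:
        if record <= onset < record + 1 or (record == 0 and onset < 0):
            tal += f"+{onset:g}\x14\x14{label}\x14\x00".encode("utf-8")
    if len(tal) > n_bytes:
        raise ValueError("annotation block overflow")
    return tal + b"\x00" * (n_bytes - len(tal))


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as EDF+C with markers as annotations."""
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    fs = int(round(fs))
    data = np.asarray(recording.data, dtype=np.float64)
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / fs))
    if n_rec * fs != n_samp:
        data = np.pad(data, ((0, 0), (0, n_rec * fs - n_samp)))

    pmax = float(np.ceil(max(np.abs(data).max(), 1.0)))
    transducer = "AgAgCl electrode"
    if pmax / _DIG_MAX > REFERENCE_LSB_UV:
        gain = (pmax / _DIG_MAX) / REFERENCE_LSB_UV
        warnings.warn(
            f"amplitude range ±{pmax:g} µV exceeds the {REFERENCE_LSB_UV} "
            f"µV/LSB reference resolution (gain {gain:.3g} recorded in "
            "transducer field)", stacklevel=2)
        transducer = f"AgAgCl electrode gain={gain:.6g}"
    pmin = -pmax

    # Annotation signal sized for the densest record's TALs.
    ann_bytes = 16
    for rec_i in range(n_rec):
        need = len(_annotation_payload(recording.markers, rec_i, 10 ** 6))
        ann_bytes = max(ann_bytes, need)
    ann_bytes = int(np.ceil(ann_bytes / 2) * 2)
    ann_samples = ann_bytes // 2

    n_sig = n_ch + 1
    header_bytes = 256 * (1 + n_sig)
    head = b""
    head += _field("0", 8)
    head += _field("X X X X", 80)
    head += _field("Startdate 01-JAN-2020 X X X", 80)
    head += _field("01.01.20", 8)
    head += _field("00.00.00", 8)
    head += _field(str(header_bytes), 8)
    head += _field("EDF+C", 44)
    head += _field(str(n_rec), 8)
    head += _field("1", 8)
    head += _field(str(n_sig), 4)

    labels = [f"EEG {c}" for c in recording.channel_labels] + ["EDF Annotations"]
    transducers = [transducer] * n_ch + [""]
    dims = ["uV"] * n_ch + [""]
    pmins = [f"{pmin:g}"] * n_ch + ["-1"]
    pmaxs = [f"{pmax:g}"] * n_ch + ["1"]
    dmins = [str(_DIG_MIN)] * n_ch + [str(_DIG_MIN)]
    dmaxs = [str(_DIG_MAX)] * n_ch + [str(_DIG_MAX)]
    prefilters = ["HP:0.2Hz LP:45Hz"] * n_ch + [""]
    samples = [str(fs)] * n_ch + [str(ann_samples)]

    for values, width in ((labels, 16), (transducers, 80), (dims, 8),
                          (pmins, 8), (pmaxs, 8), (dmins, 8), (dmaxs, 8),
                          (prefilters, 80), (samples, 8)):
        for v in values:
            head += _field(v, width)
    head += b" " * (32 * n_sig)
    assert len(head) == header_bytes

    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    body = bytearray()
    for rec_i in range(n_rec):
        block = data[:, rec_i * fs:(rec_i + 1) * fs]
        dig = np.round((block - pmin) * scale + _DIG_MIN)
        body += np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2").tobytes()
        body += _annotation_payload(recording.markers, rec_i, ann_bytes)

    Path(path).write_bytes(head + bytes(body))


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a Recording (µV, markers from annotations)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [name.removeprefix("EEG ").strip() for name in raw.ch_names]
    data = raw.get_data() * 1e6  # mne uses volts internally
    markers = [(str(desc), float(onset))
               for onset, desc in zip(raw.annotations.onset,
                                      raw.annotations.description)]
    return Recording(channel_labels=tuple(labels),
                     sampling_rate=float(raw.info["sfreq"]),
                     data=data, markers=markers,
                     meta={"source": str(path), "format": "edf"})
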