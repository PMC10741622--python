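"""Reader/writer for a constrained XDF subset.

XDF (Extensible Data Format) is the chunked container used by
lab-streaming-layer acquisition software: a magic ``XDF:`` prefix
followed by length-prefixed chunks (FileHeader, StreamHeader, Samples,
StreamFooter ...), with stream metadata as XML and samples as packed
binary.  This module implements the subset needed for EEG + marker
streams: numeric ``float32``/``double64`` signal streams with a nominal
rate and ``string`` marker streams, with optional per-sample
timestamps.  Parse failures raise :class:`XdfParseError` carrying the
byte offset.
"""

from __future__ import annotations

import struct
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

MAGIC = b"XDF:"

TAG_FILE_HEADER = 1
TAG_STREAM_HEADER = 2
TAG_SAMPLES = 3
TAG_CLOCK_OFFSET = 4
TAG_BOUNDARY = 5
TAG_STREAM_FOOTER = 6

_FORMATS = {"float32": ("<f4", 4), "double64": ("<f8", 8)}


class XdfParseError(ValueError):
    """Malformed XDF content; ``offset`` is the failing byte position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at byte offset {offset})")
        self.offset = offset


def _varlen(n: int) -> bytes:
    if n < 256:
        return b"\x01" + struct.pack("<B", n)
    return b"\x04" + struct.pack("<I", n)


class _Cursor:
    def __init__(self, buf: bytes, pos: int = 0):
        self.buf = buf
        self.pos = pos

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise XdfParseError("truncated chunk", self.pos)
        out = self.buf[self.pos:self.pos + n]
        self.pos += n
        return out

    def varlen(self) -> int:
        nbytes = self.take(1)[0]
        if nbytes == 1:
            return self.take(1)[0]
        if nbytes == 4:
            return struct.unpack("<I", self.take(4))[0]
        if nbytes == 8:
            return struct.unpack("<Q", self.take(8))[0]
        raise XdfParseError(f"invalid varlen size byte {nbytes}", self.pos - 1)


def write_xdf(path: str | Path, channel_labels, sampling_rate: float,
              data: np.ndarray, markers, channel_format: str = "double64",
              chunk_samples: int = 4096) -> None:
    """Write an EEG stream (stream id 1) and a marker stream (id 2).

    ``data`` is channels x samples in µV; ``markers`` is a list of
    (label, onset_seconds).  Timestamps start at 0.
    """
    if channel_format not in _FORMATS:
        raise ValueError(f"channel_format must be one of {list(_FORMATS)}")
    dtype, _ = _FORMATS[channel_format]
    data = np.asarray(data)
    n_ch, n_samp = data.shape

    def chunk(tag: int, payload: bytes) -> bytes:
        return _varlen(len(payload) + 2) + struct.pack("<H", tag) + payload

    out = bytearray(MAGIC)
    out += chunk(TAG_FILE_HEADER,
                 b"<?xml version=\"1.0\"?><info><version>1.0</version></info>")

    chans = "".join(
        f"<channel><label>{c}</label><unit>microvolts</unit></channel>"
        for c in channel_labels)
    eeg_hdr = (f"<?xml version=\"1.0\"?><info><name>EEG</name><type>EEG</type>"
               f"<channel_count>{n_ch}</channel_count>"
               f"<nominal_srate>{sampling_rate:g}</nominal_srate>"
               f"<channel_format>{channel_format}</channel_format>"
               f"<desc><channels>{chans}</channels></desc></info>")
    out += chunk(TAG_STREAM_HEADER, struct.pack("<I", 1) + eeg_hdr.encode())

    mrk_hdr = ("<?xml version=\"1.0\"?><info><name>Markers</name>"
               "<type>Markers</type><channel_count>1</channel_count>"
               "<nominal_srate>0</nominal_srate>"
               "<channel_format>string</channel_format></info>")
    out += chunk(TAG_STREAM_HEADER, struct.pack("<I", 2) + mrk_hdr.encode())

    cols = np.ascontiguousarray(data.T.astype(dtype))  # sample-major
    for start in range(0, n_samp, chunk_samples):
        block = cols[start:start + chunk_samples]
        payload = bytearray(struct.pack("<I", 1) + _varlen(len(block)))
        for i, row in enumerate(block):
            if i == 0:
                payload += b"\x08" + struct.pack(
                    "<d", (start + i) / sampling_rate)
            else:
                payload += b"\x00"
            payload += row.tobytes()
        out += chunk(TAG_SAMPLES, bytes(payload))

    if markers:
        payload = bytearray(struct.pack("<I", 2) + _varlen(len(markers)))
        for label, onset in markers:
            enc = str(label).encode("utf-8")
            payload += b"\x08" + struct.pack("<d", float(onset))
            payload += _varlen(len(enc)) + enc
        out += chunk(TAG_SAMPLES, bytes(payload))

    Path(path).write_bytes(bytes(out))


def read_xdf(path: str | Path) -> dict:
    """Parse the XDF subset into streams.

    Returns ``{"eeg": {"labels", "srate", "data", "t0"},
    "markers": [(label, onset_relative_to_eeg_start), ...]}``.
    """
    buf = Path(path).read_bytes()
    if buf[:4] != MAGIC:
        raise XdfParseError("missing XDF magic", 0)
    cur = _Cursor(buf, 4)

    headers: dict[int, dict] = {}
    samples: dict[int, list] = {}
    timestamps: dict[int, list] = {}

    while cur.pos < len(buf):
        chunk_start = cur.pos
        length = cur.varlen()
        if length < 2:
            raise XdfParseError(f"chunk length {length} too small", chunk_start)
        body = _Cursor(cur.take(length), 0)
        tag = struct.unpack("<H", body.take(2))[0]
        if tag in (TAG_FILE_HEADER, TAG_BOUNDARY, TAG_CLOCK_OFFSET,
                   TAG_STREAM_FOOTER):
            continue
        if tag == TAG_STREAM_HEADER:
            sid = struct.unpack("<I", body.take(4))[0]
            xml = body.buf[body.pos:].decode("utf-8", "replace")
            try:
                info = ElementTree.fromstring(xml)
            except ElementTree.ParseError as exc:
                raise XdfParseError(f"bad stream header XML: {exc}",
                                    chunk_start) from None
            fmt = info.findtext("channel_format", "double64")
            labels = [el.text for el in info.findall("desc/channels/channel/label")]
            headers[sid] = {
                "name": info.findtext("name", ""),
                "type": info.findtext("type", ""),
                "n_ch": int(info.findtext("channel_count", "1")),
                "srate": float(info.findtext("nominal_srate", "0")),
                "format": fmt,
                "labels": labels,
            }
            samples[sid] = []
            timestamps[sid] = []
        elif tag == TAG_SAMPLES:
            sid = struct.unpack("<I", body.take(4))[0]
            if sid not in headers:
                raise XdfParseError(f"samples for unknown stream {sid}",
                                    chunk_start)
            h = headers[sid]
            n = body.varlen()
            last_ts = timestamps[sid][-1] if timestamps[sid] else None
            dt = 1.0 / h["srate"] if h["srate"] > 0 else 0.0
            for _ in range(n):
                has_ts = body.take(1)[0]
                if has_ts == 8:
                    ts = struct.unpack("<d", body.take(8))[0]
                elif has_ts == 0:
                    if last_ts is None:
                        raise XdfParseError("first sample lacks timestamp",
                                            chunk_start)
                    ts = last_ts + dt
                else:
                    raise XdfParseError(
                        f"invalid timestamp flag {has_ts}",
                        chunk_start + body.pos - 1)
                last_ts = ts
                timestamps[sid].append(ts)
                if h["format"] == "string":
                    slen = body.varlen()
                    samples[sid].append(body.take(slen).decode("utf-8"))
                elif h["format"] in _FORMATS:
                    dtype, size = _FORMATS[h["format"]]
                    raw = body.take(h["n_ch"] * size)
                    samples[sid].append(np.frombuffer(raw, dtype=dtype))
                else:
                    raise XdfParseError(
                        f"unsupported channel format {h['format']!r}",
                        chunk_start)
        else:
            raise XdfParseError(f"unknown chunk tag {tag}", chunk_start)

    eeg_sid = next((sid for sid, h in headers.items()
                    if h["type"].lower() == "eeg"), None)
    if eeg_sid is None:
        raise XdfParseError("no EEG stream found", len(buf))
    h = headers[eeg_sid]
    if not samples[eeg_sid]:
        raise XdfParseError("EEG stream has no samples", len(buf))
    data = np.vstack(samples[eeg_sid]).T.astype(np.float64)
    t0 = timestamps[eeg_sid][0]

    marks: list[tuple[str, float]] = []
    for sid, hh in headers.items():
        if hh["format"] == "string":
            marks.extend((lab, ts - t0)
                         for lab, ts in zip(samples[sid], timestamps[sid]))
    marks.sort(key=lambda m: m[1])
    return {"eeg": {"labels": h["labels"], "srate": h["srate"],
                    "data": data, "t0": t0},
            "markers": marks}
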