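"""Reading and writing recordings: EDF+, XDF subset, fixture CSV.

The fixture CSV dialect is the diffable test format: one row per
sample, first column ``time`` in seconds, one column per channel in
µV; markers and metadata live in a JSON sidecar next to the CSV
(``<stem>.markers.json``).  EDF+ carries markers as annotations; the
XDF subset carries them as a string marker stream.

All readers return channels reordered into the canonical montage order
and fail loudly (naming the channels) when montage channels are
missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf, _xdf
from .recording import Recording, reorder_canonical

FORMATS = ("fixture-csv", "edf", "xdf")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".markers.json")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "fixture-csv"
    if suffix == ".edf":
        return "edf"
    if suffix == ".xdf":
        return "xdf"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; "
                     f"pass format= one of {FORMATS}")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording, reorder channels canonically, units in µV."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "fixture-csv":
        frame = pd.read_csv(path, float_precision="round_trip")
        if frame.columns[0] != "time":
            raise ValueError("fixture CSV must start with a 'time' column")
        labels = tuple(frame.columns[1:])
        dt = np.diff(frame["time"].to_numpy()[:2])
        fs = 1.0 / dt[0] if len(dt) else 256.0
        markers: list[tuple[str, float]] = []
        meta: dict = {}
        side = _sidecar(path)
        if side.exists():
            info = json.loads(side.read_text())
            markers = [(m["label"], float(m["onset"])) for m in info["markers"]]
            fs = float(info.get("sampling_rate", fs))
            meta = info.get("meta", {})
        rec = Recording(channel_labels=labels, sampling_rate=fs,
                        data=frame[list(labels)].to_numpy().T,
                        markers=markers,
                        meta={**meta, "source": str(path),
                              "format": "fixture-csv"})
    elif fmt == "edf":
        rec = _edf.read_edf(path)
    elif fmt == "xdf":
        parsed = _xdf.read_xdf(path)
        eeg = parsed["eeg"]
        rec = Recording(channel_labels=tuple(eeg["labels"]),
                        sampling_rate=eeg["srate"], data=eeg["data"],
                        markers=parsed["markers"],
                        meta={"source": str(path), "format": "xdf"})
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    return reorder_canonical(rec)


def write_recording(recording: Recording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording as fixture CSV (+ JSON sidecar), EDF+ or XDF."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "fixture-csv":
        t = np.arange(recording.n_samples) / recording.sampling_rate
        frame = pd.DataFrame({"time": t})
        for label, row in zip(recording.channel_labels, recording.data):
            frame[label] = row
        # %.17g round-trips float64 exactly -> diffable, bit-stable fixtures
        frame.to_csv(path, index=False, float_format="%.17g")
        meta = {k: v for k, v in recording.meta.items()
                if isinstance(v, (str, int, float, bool))}
        _sidecar(path).write_text(json.dumps({
            "sampling_rate": recording.sampling_rate,
            "markers": [{"label": lab, "onset": onset}
                        for lab, onset in recording.markers],
            "meta": meta,
        }, indent=1))
    elif fmt == "edf":
        _edf.write_edf(recording, path)
    elif fmt == "xdf":
        _xdf.write_xdf(path, recording.channel_labels,
                       recording.sampling_rate, recording.data,
                       recording.markers)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
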