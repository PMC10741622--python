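"""In-memory EEG recording container and montage validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .montage import CHANNELS, MARKER_TO_TASK, normalize_marker


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    channel_labels : tuple of str
        Montage channel names, one per data row, in canonical order.
    sampling_rate : float
        Samples per second (Hz).
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    markers : list of (label, onset_seconds)
        Timed event markers delimiting the task segments.
    meta : dict
        Free-form provenance (participant id, group, generator seed, ...).
    """

    channel_labels: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray
    markers: list[tuple[str, float]] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} data rows")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Signal of one channel by montage label."""
        return self.data[self.channel_labels.index(label)]

    def copy(self) -> "Recording":
        return Recording(
            channel_labels=tuple(self.channel_labels),
            sampling_rate=self.sampling_rate,
            data=self.data.copy(),
            markers=list(self.markers),
            meta=dict(self.meta),
        )


def reorder_canonical(recording: Recording) -> Recording:
    """Return a copy with channels permuted into canonical montage order.

    Raises ``ValueError`` naming any montage channel that is missing.
    Extra non-montage channels are dropped.
    """
    have = {lab: i for i, lab in enumerate(recording.channel_labels)}
    missing = [c for c in CHANNELS if c not in have]
    if missing:
        raise ValueError(f"missing montage channels: {', '.join(missing)}")
    idx = [have[c] for c in CHANNELS]
    return Recording(
        channel_labels=CHANNELS,
        sampling_rate=recording.sampling_rate,
        data=recording.data[idx],
        markers=list(recording.markers),
        meta=dict(recording.meta),
    )


def validate_montage(recording: Recording) -> list[str]:
    """Report montage, marker and sample-quality issues.

    Returns a list of human-readable issue strings; an empty list means
    the recording is canonical: all 14 montage channels present, the four
    expected segment markers covered, and every sample finite.  This is a
    report-only check; nothing is modified.
    """
    issues: list[str] = []
    have = list(recording.channel_labels)
    for c in CHANNELS:
        if c not in have:
            issues.append(f"missing channel {c}")
    for c in have:
        if c not in CHANNELS:
            issues.append(f"extra non-montage channel {c}")
    if have.count(None) == 0 and len(set(have)) != len(have):
        dupes = sorted({c for c in have if have.count(c) > 1})
        issues.append(f"duplicate channels: {', '.join(dupes)}")

    seen = {normalize_marker(lab) for lab, _ in recording.markers}
    for marker, task in MARKER_TO_TASK.items():
        if marker not in seen:
            issues.append(f"missing segment marker '{marker}' ({task})")
    for lab, onset in recording.markers:
        if normalize_marker(lab) not in MARKER_TO_TASK:
            issues.append(f"unknown marker label '{lab}' at {onset:g} s")
        if not 0.0 <= onset <= recording.duration:
            issues.append(f"marker '{lab}' onset {onset:g} s outside recording")

    bad = ~np.isfinite(recording.data)
    if bad.any():
        ch_idx, s_idx = np.argwhere(bad)[0]
        issues.append(
            f"non-finite sample at channel {recording.channel_labels[ch_idx]} "
            f"index {s_idx} ({int(bad.sum())} total)")
    return issues
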