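"""Task segmentation, 1-s epoching and threshold-based artifact rejection.

The exam protocol yields four contiguous segments — a 3-min eyes-open
baseline, 3 min of reading the case stem, 12 min of questioning on that
case ("answer 1") and 3 min on a spontaneously presented second case
("answer 2").  Each segment is cut into non-overlapping 1-second epochs;
epochs containing large transients (head/muscle movement) are masked out
before any spectral estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .montage import MARKER_TO_TASK, TASKS, normalize_marker
from .recording import Recording

#: Default rejection thresholds (microvolts).  Standard quantitative-EEG
#: practice: absolute deviation from the epoch mean, peak-to-peak range,
#: and a flatline floor for dead channels.
DEFAULT_ABS_THRESH = 100.0
DEFAULT_PTP_THRESH = 200.0
DEFAULT_FLAT_THRESH = 0.1


@dataclass
class EpochSet:
    """Fixed-length epochs of one task segment for one participant.

    ``epochs`` has shape (n_epochs, n_channels, n_samples) with each
    epoch exactly one second long.  ``artifact_mask`` is True for epochs
    flagged as contaminated; "retained" epochs are the mask-False ones.
    """

    task: str
    epochs: np.ndarray
    sampling_rate: float
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    participant: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        if self.epochs.dtype not in (np.float32, np.float64):
            self.epochs = self.epochs.astype(np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x channel x sample)")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.epochs), dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.artifact_mask) != len(self.epochs):
            raise ValueError("mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.artifact_mask).sum())

    def retained(self) -> np.ndarray:
        """The clean epochs (mask False), shape (n_retained, ch, samp)."""
        return self.epochs[~self.artifact_mask]


def segment_tasks(recording: Recording) -> dict[str, tuple[float, float]]:
    """Locate the four task segments from the recording's markers.

    Each segment spans from its marker onset to the next marker (or the
    end of the recording for the last segment).  Marker labels are
    matched case-insensitively after whitespace normalization.

    Returns a mapping ``task -> (start_s, end_s)`` for the tasks
    baseline, reading, answer1, answer2.

    Raises
    ------
    ValueError
        If a segment marker is missing or duplicated, or markers are out
        of chronological order.
    """
    onsets: dict[str, float] = {}
    for label, onset in recording.markers:
        task = MARKER_TO_TASK.get(normalize_marker(label))
        if task is None:
            continue  # unknown markers are tolerated here; validate_montage flags them
        if task in onsets:
            raise ValueError(f"duplicated segment marker for task '{task}'")
        onsets[task] = float(onset)

    missing = [t for t in TASKS if t not in onsets]
    if missing:
        raise ValueError(f"missing segment marker(s): {', '.join(missing)}")

    order = sorted(TASKS, key=lambda t: onsets[t])
    if tuple(order) != TASKS:
        raise ValueError(
            f"segment markers out of order: found {order}, expected {list(TASKS)}")

    bounds: dict[str, tuple[float, float]] = {}
    for i, task in enumerate(TASKS):
        start = onsets[task]
        end = onsets[TASKS[i + 1]] if i + 1 < len(TASKS) else recording.duration
        end = min(end, recording.duration)
        if end <= start:
            raise ValueError(f"segment '{task}' has non-positive duration")
        bounds[task] = (start, end)
    return bounds


def epoch_segment(
    recording: Recording,
    interval: tuple[float, float],
    length: float = 1.0,
    task: str = "",
    participant: str = "",
) -> EpochSet:
    """Cut ``interval`` (seconds) into non-overlapping epochs of ``length`` s.

    ``floor(duration / length)`` epochs are produced; a leftover tail
    shorter than one epoch is discarded.  All artifact masks start False.
    An interval shorter than one epoch yields an empty set with a warning.
    """
    start, end = interval
    fs = recording.sampling_rate
    if not (0.0 <= start < end <= recording.duration + 1e-9):
        raise ValueError(f"interval {interval} outside recording "
                         f"[0, {recording.duration:g}]")
    n_samp = int(round(length * fs))
    i0 = int(round(start * fs))
    n_avail = int(np.floor((end - start) * fs + 1e-9))
    n_ep = n_avail // n_samp
    if n_ep == 0:
        warnings.warn(f"interval {interval} shorter than one {length:g}-s epoch; "
                      "empty epoch set", stacklevel=2)
    block = recording.data[:, i0:i0 + n_ep * n_samp]
    # (ch, n_ep * n_samp) -> (n_ep, ch, n_samp)
    epochs = block.reshape(recording.n_channels, n_ep, n_samp).swapaxes(0, 1)
    return EpochSet(task=task, epochs=epochs.copy(), sampling_rate=fs,
                    participant=participant)


def reject_artifacts(
    epochs: EpochSet,
    abs_thresh: float = DEFAULT_ABS_THRESH,
    ptp_thresh: float = DEFAULT_PTP_THRESH,
    flat_thresh: float = DEFAULT_FLAT_THRESH,
) -> EpochSet:
    """Flag contaminated epochs by amplitude criteria.

    An epoch is masked when any channel in it exceeds
    ``|x - epoch_channel_mean| > abs_thresh``, has peak-to-peak range
    above ``ptp_thresh``, or is flat (peak-to-peak below ``flat_thresh``).
    Decisions depend only on the epoch's own samples.  Returns a new
    :class:`EpochSet` whose mask is the OR of the existing mask and the
    new flags (stricter thresholds never unmask).
    """
    if min(abs_thresh, ptp_thresh, flat_thresh) <= 0:
        raise ValueError("thresholds must be positive")
    x = epochs.epochs
    centred = x - x.mean(axis=2, keepdims=True)
    dev = np.abs(centred).max(axis=2)          # (n_ep, ch)
    ptp = x.max(axis=2) - x.min(axis=2)        # (n_ep, ch)
    flag = ((dev > abs_thresh) | (ptp > ptp_thresh) | (ptp < flat_thresh)).any(axis=1)
    return EpochSet(
        task=epochs.task,
        epochs=epochs.epochs,
        sampling_rate=epochs.sampling_rate,
        artifact_mask=epochs.artifact_mask | flag,
        participant=epochs.participant,
    )


def override_mask(epochs: EpochSet,
                  force_reject: tuple[int, ...] = (),
                  force_keep: tuple[int, ...] = ()) -> EpochSet:
    """Manually override automatic rejection decisions.

    Artifact screening in practice has a manual review step; this
    applies a reviewer's decisions on top of the automatic mask.
    Indices in ``force_reject`` are masked, ``force_keep`` unmasked;
    an index in both is rejected (conservative).
    """
    mask = epochs.artifact_mask.copy()
    for idx in force_keep:
        mask[idx] = False
    for idx in force_reject:
        mask[idx] = True
    return EpochSet(task=epochs.task, epochs=epochs.epochs,
                    sampling_rate=epochs.sampling_rate, artifact_mask=mask,
                    participant=epochs.participant)


def preprocess_recording(
    recording: Recording,
    abs_thresh: float = DEFAULT_ABS_THRESH,
    ptp_thresh: float = DEFAULT_PTP_THRESH,
    flat_thresh: float = DEFAULT_FLAT_THRESH,
) -> dict[str, EpochSet]:
    """Segment, epoch and artifact-reject a whole recording.

    Returns one :class:`EpochSet` per task with masks already updated.
    A participant failing more than 50% of epochs in any task is flagged
    with a warning (never silently dropped).
    """
    pid = str(recording.meta.get("participant", ""))
    out: dict[str, EpochSet] = {}
    for task, interval in segment_tasks(recording).items():
        es = epoch_segment(recording, interval, task=task, participant=pid)
        es = reject_artifacts(es, abs_thresh, ptp_thresh, flat_thresh)
        if es.n_epochs and es.artifact_mask.mean() > 0.5:
            warnings.warn(
                f"participant {pid or '<unknown>'}: >50% of '{task}' epochs "
                "rejected; inspect recording", stacklevel=2)
        out[task] = es
    return out
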