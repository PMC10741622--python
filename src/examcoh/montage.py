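"""Electrode montage and task-segment conventions.

The recordings come from a 14-channel saline-electrode headset using a
10-20 subset (mastoid referenced, P3/P4 as references).  The channel
listing order below is the canonical order used everywhere in the
package: feature vectors, pair indices and file channel order all refer
to it, which makes the 91-pair coherence feature layout deterministic.
"""

from __future__ import annotations

from itertools import combinations

#: Canonical channel order of the 14-channel montage.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Posterior channels that carry the low-amplitude resting alpha rhythm
#: in the synthetic generator.
POSTERIOR_CHANNELS: tuple[str, ...] = ("P7", "O1", "O2", "P8")

#: Internal task labels in exam order.
TASKS: tuple[str, ...] = ("baseline", "reading", "answer1", "answer2")

#: Marker labels as written into recordings, mapped to task labels.
#: Matching is case-insensitive after whitespace normalization.
MARKER_TO_TASK: dict[str, str] = {
    "eyes open": "baseline",
    "reading": "reading",
    "answer 1": "answer1",
    "answer 2": "answer2",
}

TASK_TO_MARKER: dict[str, str] = {v: k for k, v in MARKER_TO_TASK.items()}


def normalize_marker(label: str) -> str:
    """Normalize a marker label: collapse whitespace, lowercase."""
    return " ".join(label.split()).lower()


def channel_index(label: str) -> int:
    """Index of *label* in the canonical montage order."""
    try:
        return CHANNELS.index(label)
    except ValueError:
        raise KeyError(f"{label!r} is not a montage channel; "
                       f"expected one of {CHANNELS}") from None


def canonical_pairs() -> list[tuple[str, str]]:
    """All 91 unordered channel pairs in canonical (montage-order) listing."""
    return list(combinations(CHANNELS, 2))


def pair_name(a: str, b: str) -> str:
    """Canonical name of an unordered channel pair, e.g. ``"FC5-FC6"``.

    The two channels are ordered by montage position, so the name is
    independent of argument order.
    """
    ia, ib = channel_index(a), channel_index(b)
    if ia == ib:
        raise ValueError(f"pair requires two distinct channels, got {a!r} twice")
    if ia > ib:
        a, b = b, a
    return f"{a}-{b}"


N_PAIRS = len(canonical_pairs())  # 91 = C(14, 2)
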