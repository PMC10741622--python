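"""Participant-by-feature tables and their normalization pipeline.

A feature is one scalar per participant named
``task.band.kind.channels`` — e.g. ``reading.theta.coh.FC5-FC6`` (band
coherence of a channel pair) or ``answer2.alpha.psd.F3`` (band power at
one channel).  Per task and band there are exactly 91 coherence features
(all channel pairs) and 14 PSD features (all channels).

Processing stages follow the study's order: raw band features per task,
subtraction of the same participant's eyes-open baseline value for every
feature (controls for individual signal differences and isolates
task-related change), then min-max scaling of each feature column across
participants onto [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import CHANNELS, TASKS, pair_name
from .preprocess import EpochSet
from .spectral import (DEFAULT_BANDS, DEFAULT_KAISER_BETA, BandDefinition,
                       _coherence_from_spectra, _psd_from_spectra,
                       _windowed_spectra, band_power)

STAGES = ("raw", "baseline_corrected", "normalized")


@dataclass
class FeatureTable:
    """Participant x feature matrix with group labels and a stage tag.

    ``values`` is a DataFrame indexed by participant id; ``groups`` is a
    participant-aligned Series with labels ``"experienced"``/``"novice"``.
    ``task`` is set for single-task tables (columns then omit the task
    prefix) and None for combined multi-task tables.
    """

    values: pd.DataFrame
    groups: pd.Series
    stage: str = "raw"
    task: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = list(self.values.index[self.groups.isna()])
            raise ValueError(f"missing group labels for participants {missing}")

    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.groups.copy(),
                            self.stage, self.task)


def feature_vector(epochs: EpochSet,
                   bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                   kaiser_beta: float = DEFAULT_KAISER_BETA) -> pd.Series:
    """All band features of one participant's task segment.

    Column names are ``band.kind.channels`` (no task prefix); the order
    is bands x (14 PSD channels, then 91 coherence pairs), deterministic.
    PSD and coherence share one pass of Kaiser-windowed epoch spectra.
    """
    if epochs.epochs.shape[1] != len(CHANNELS):
        raise ValueError("feature_vector expects the 14-channel montage "
                         f"(got {epochs.epochs.shape[1]} channels)")
    if epochs.n_retained < 2:
        raise ValueError("need >=2 retained epochs for coherence features "
                         f"(participant {epochs.participant!r}, "
                         f"task {epochs.task!r})")
    freqs, X, U = _windowed_spectra(epochs, kaiser_beta)
    psd = _psd_from_spectra(X, U, epochs.sampling_rate, epochs.epochs.shape[2])
    coh = _coherence_from_spectra(X)
    iu = np.triu_indices(len(CHANNELS), k=1)
    pairs = [pair_name(CHANNELS[i], CHANNELS[j]) for i, j in zip(*iu)]
    out: dict[str, float] = {}
    for band in bands:
        sel = band.bins(freqs)
        bp = band_power(psd, freqs, band)
        for ch, value in zip(CHANNELS, bp):
            out[f"{band.name}.psd.{ch}"] = float(value)
        band_coh = coh[:, :, sel].mean(axis=2)[iu]
        for pair, value in zip(pairs, band_coh):
            out[f"{band.name}.coh.{pair}"] = float(value)
    return pd.Series(out)


def cohort_feature_tables(
    epochsets: dict[str, dict[str, EpochSet]],
    groups: dict[str, str],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    kaiser_beta: float = DEFAULT_KAISER_BETA,
) -> dict[str, FeatureTable]:
    """Raw per-task feature tables for a cohort.

    ``epochsets`` maps participant id -> task -> EpochSet.  Returns one
    raw-stage :class:`FeatureTable` per task (including baseline).
    """
    rows: dict[str, dict[str, pd.Series]] = {t: {} for t in TASKS}
    for pid, by_task in epochsets.items():
        for task, es in by_task.items():
            rows[task][pid] = feature_vector(es, bands, kaiser_beta)
    group_series = pd.Series(groups, name="group")
    return {
        task: FeatureTable(pd.DataFrame.from_dict(per_pid, orient="index")
                           .sort_index(), group_series, "raw", task)
        for task, per_pid in rows.items() if per_pid
    }


def baseline_correct(task_features: FeatureTable,
                     baseline_features: FeatureTable) -> FeatureTable:
    """Subtract each participant's eyes-open baseline value per feature.

    Both tables must be single-task, raw-stage tables over the same
    participants and feature columns.  Outputs may be negative.
    """
    missing = [p for p in task_features.participants
               if p not in baseline_features.values.index]
    if missing:
        raise ValueError(f"participants missing a baseline: {missing}")
    if list(task_features.values.columns) != list(baseline_features.values.columns):
        raise ValueError("task and baseline tables have different feature columns")
    corrected = (task_features.values
                 - baseline_features.values.loc[task_features.participants])
    return FeatureTable(corrected, task_features.groups,
                        "baseline_corrected", task_features.task)


def minmax_normalize(table: FeatureTable) -> FeatureTable:
    """Min-max scale every feature column across participants onto [0, 1].

    A constant column carries no between-participant information and is
    mapped to all zeros with a warning.
    """
    if len(table.values) < 2:
        raise ValueError("min-max scaling needs >=2 participants")
    x = table.values
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = hi - lo
    constant = span <= 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature column(s) "
                      "mapped to 0", stacklevel=2)
    span = span.where(~constant, 1.0)
    scaled = (x - lo) / span
    scaled.loc[:, constant] = 0.0
    return FeatureTable(scaled, table.groups, "normalized", table.task)


def combine_tasks(tables: dict[str, FeatureTable],
                  tasks: tuple[str, ...] = ("reading", "answer1", "answer2")
                  ) -> FeatureTable:
    """Join per-task tables into one wide table with task-prefixed columns."""
    parts = []
    stage = None
    groups = None
    for task in tasks:
        t = tables[task]
        stage = stage or t.stage
        if t.stage != stage:
            raise ValueError("cannot combine tables at different stages")
        groups = t.groups if groups is None else groups
        renamed = t.values.add_prefix(f"{task}.")
        parts.append(renamed)
    values = pd.concat(parts, axis=1)
    return FeatureTable(values, groups, stage, None)


def parse_feature_name(name: str) -> dict[str, str]:
    """Split ``task.band.kind.channels`` into its components."""
    parts = name.split(".")
    if len(parts) != 4 or parts[2] not in ("psd", "coh"):
        raise ValueError(f"malformed feature name {name!r}")
    return {"task": parts[0], "band": parts[1], "kind": parts[2],
            "channels": parts[3]}
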