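"""End-to-end orchestration: simulate -> preprocess -> features -> stats.

One master seed fans out to per-stage seeds by fixed offsets, so a full
run is bit-identical across reruns and the run log suffices to
reproduce every number in the bundle.  The emitted bundle contains the
feature tables at each stage, a group-comparison table (significant
coherence contrasts formatted like the study's summary table), the two
outcome models (performance and cognitive load), a connectivity edge
list for plotting, and a JSON run log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import ICCResult, rater_agreement, score_behavior
from .features import (FeatureTable, baseline_correct, combine_tasks,
                       cohort_feature_tables, minmax_normalize)
from .preprocess import (DEFAULT_ABS_THRESH, DEFAULT_FLAT_THRESH,
                         DEFAULT_PTP_THRESH, preprocess_recording)
from .simulate import (BehaviorTruth, Cohort, CohortConfig, simulate_behavior,
                       simulate_cohort)
from .spectral import DEFAULT_KAISER_BETA, DEFAULT_REPORT_BANDS
from .stats import ModelFit, compare_groups, fit_outcome_model

EXAM_TASKS = ("reading", "answer1", "answer2")

# Fixed offsets fanning the master seed out to stages.
_SEED_OFFSET_BEHAVIOR = 17
_SEED_OFFSET_FOLDS = 29


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults mirror the study conditions."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    master_seed: int = 7
    abs_thresh: float = DEFAULT_ABS_THRESH
    ptp_thresh: float = DEFAULT_PTP_THRESH
    flat_thresh: float = DEFAULT_FLAT_THRESH
    kaiser_beta: float = DEFAULT_KAISER_BETA
    normalization_scope: str = "per_task"      # or "pooled_tasks"
    test_variant: str = "pooled"               # or "welch"
    bh_correction: bool = False
    alpha: float = 0.05
    lasso_folds: int = 5
    report_bands: tuple[str, ...] = DEFAULT_REPORT_BANDS

    def __post_init__(self) -> None:
        if self.normalization_scope not in ("per_task", "pooled_tasks"):
            raise ValueError("normalization_scope must be per_task or "
                             "pooled_tasks")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_kwargs = raw.pop("cohort", {})
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        if cohort_kwargs:
            cfg.cohort = replace(cfg.cohort, **cohort_kwargs)
        return cfg


def _derived_seed(master: int, offset: int) -> int:
    return int(np.random.SeedSequence([master & 0x7FFFFFFF, offset])
               .generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunResult:
    """In-memory bundle of one end-to-end run."""

    config: PipelineConfig
    cohort: Cohort
    features_raw: FeatureTable
    features_corrected: FeatureTable
    features_normalized: FeatureTable
    behavior: pd.DataFrame
    behavior_truth: BehaviorTruth
    scores: pd.DataFrame
    icc: ICCResult
    comparison: pd.DataFrame
    edges: pd.DataFrame
    model_performance: ModelFit
    model_tlx: ModelFit
    rejection_rates: dict[str, float]
    log: dict


def normalize_tables(corrected: dict[str, FeatureTable],
                     scope: str = "per_task") -> FeatureTable:
    """Min-max normalize corrected per-task tables and combine them.

    ``per_task`` scales each task's feature column independently across
    participants (default).  ``pooled_tasks`` scales each
    ``band.kind.channels`` feature jointly over participants x tasks.
    """
    if scope == "per_task":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant columns are expected
            normalized = {t: minmax_normalize(tab)
                          for t, tab in corrected.items()}
        return combine_tasks(normalized, EXAM_TASKS)
    stacked = pd.concat([corrected[t].values for t in EXAM_TASKS])
    lo, hi = stacked.min(axis=0), stacked.max(axis=0)
    span = (hi - lo).where(hi > lo, 1.0)
    scaled = {}
    for t in EXAM_TASKS:
        vals = (corrected[t].values - lo) / span
        scaled[t] = FeatureTable(vals.clip(0, 1), corrected[t].groups,
                                 "normalized", t)
    return combine_tasks(scaled, EXAM_TASKS)


def significant_edges(comparison: pd.DataFrame,
                      group_order=("experienced", "novice")) -> pd.DataFrame:
    """Connectivity edge list of significant coherence contrasts."""
    g1, g2 = group_order
    coh = comparison[(comparison["kind"] == "coh")
                     & comparison["significant"]].copy()
    ch = coh["channels"].str.split("-", expand=True)
    if coh.empty:
        return pd.DataFrame(columns=["task", "band", "channel1", "channel2",
                                     "direction", "p"])
    coh["channel1"], coh["channel2"] = ch[0], ch[1]
    coh["direction"] = np.where(coh[f"mean_{g1}"] > coh[f"mean_{g2}"],
                                f"{g1}>{g2}", f"{g2}>{g1}")
    return coh[["task", "band", "channel1", "channel2", "direction",
                "p"]].reset_index(drop=True)


def render_comparison_table(comparison: pd.DataFrame,
                            group_order=("experienced", "novice")
                            ) -> pd.DataFrame:
    """Significant coherence rows in the study's summary-table layout.

    Columns: task, band, per-group "mean (SD)", the two channels and the
    p-value formatted to three decimals.
    """
    g1, g2 = group_order
    rows = []
    sig = comparison[(comparison["kind"] == "coh") & comparison["significant"]]
    for _, r in sig.iterrows():
        c1, c2 = r["channels"].split("-")
        rows.append({
            "Task": r["task"],
            "Frequency Band": r["band"],
            f"{g1.capitalize()} Mean (SD)":
                f"{r[f'mean_{g1}']:.2f} ({r[f'sd_{g1}']:.2f})",
            f"{g2.capitalize()} Mean (SD)":
                f"{r[f'mean_{g2}']:.2f} ({r[f'sd_{g2}']:.2f})",
            "Coherence Channel 1": c1,
            "Coherence Channel 2": c2,
            "p-Value": f"{r['p']:.3f}",
        })
    cols = ["Task", "Frequency Band", f"{g1.capitalize()} Mean (SD)",
            f"{g2.capitalize()} Mean (SD)", "Coherence Channel 1",
            "Coherence Channel 2", "p-Value"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> RunResult:
    """Execute the full study pipeline on a synthetic cohort.

    When ``out_dir`` is given the bundle is written there: feature TSVs,
    behavior CSV, scores TSV, group-comparison and rendered tables,
    model JSONs, edge list and run log.
    """
    cohort_cfg = replace(config.cohort, seed=config.master_seed)
    cohort = simulate_cohort(cohort_cfg)

    epochsets = {}
    rejection: dict[str, float] = {}
    for pid, rec in cohort.recordings.items():
        try:
            by_task = preprocess_recording(rec, config.abs_thresh,
                                           config.ptp_thresh,
                                           config.flat_thresh)
        except ValueError as exc:
            raise RuntimeError(
                f"preprocess failed for participant {pid}: {exc}") from exc
        epochsets[pid] = by_task
        exam = [by_task[t].artifact_mask for t in EXAM_TASKS]
        rejection[pid] = float(np.concatenate(exam).mean())

    tables = cohort_feature_tables(epochsets, cohort.groups,
                                   kaiser_beta=config.kaiser_beta)
    corrected = {t: baseline_correct(tables[t], tables["baseline"])
                 for t in EXAM_TASKS}
    features_raw = combine_tasks(tables, EXAM_TASKS)
    features_corrected = combine_tasks(corrected, EXAM_TASKS)
    features_normalized = normalize_tables(corrected,
                                           config.normalization_scope)

    behavior_seed = _derived_seed(config.master_seed, _SEED_OFFSET_BEHAVIOR)
    behavior, truth = simulate_behavior(cohort_cfg, features_normalized,
                                        behavior_seed)
    scores = score_behavior(behavior)
    icc = rater_agreement(scores)

    comparison = compare_groups(features_normalized,
                                variant=config.test_variant,
                                alpha=config.alpha,
                                bh_correction=config.bh_correction,
                                report_bands=config.report_bands)
    edges = significant_edges(comparison)

    fold_seed = _derived_seed(config.master_seed, _SEED_OFFSET_FOLDS)
    # Model candidates come from the reported bands only (delta stays out
    # of the tables, mirroring the group-comparison reports).
    from .features import parse_feature_name

    n_participants = len(features_normalized.values)
    folds = config.lasso_folds
    if n_participants < folds:
        warnings.warn(f"only {n_participants} participants; reducing CV "
                      f"folds from {folds} to {n_participants}", stacklevel=2)
        folds = n_participants

    model_cols = [c for c in features_normalized.values.columns
                  if parse_feature_name(c)["band"] in config.report_bands]
    model_table = FeatureTable(features_normalized.values[model_cols],
                               features_normalized.groups, "normalized")
    model_perf = fit_outcome_model(model_table, scores["performance"],
                                   "performance", folds=folds,
                                   seed=fold_seed, screen_alpha=config.alpha)
    model_tlx = fit_outcome_model(model_table, scores["tlx_fraction"],
                                  "tlx", folds=folds,
                                  seed=fold_seed, screen_alpha=config.alpha)

    import examcoh

    log = {
        "master_seed": config.master_seed,
        "stage_seeds": {"cohort": config.master_seed,
                        "behavior": behavior_seed, "folds": fold_seed},
        "versions": {"examcoh": examcoh.__version__,
                     "numpy": np.__version__},
        "n_per_group": cohort_cfg.n_per_group,
        "artifact_rate_configured": cohort_cfg.artifact_rate,
        "rejection_rates": rejection,
        "icc": {"icc": icc.icc, "f": icc.f, "df": [icc.df1, icc.df2],
                "ci": [icc.ci_low, icc.ci_high]},
        "n_significant_features": int(comparison["significant"].sum()),
    }

    result = RunResult(
        config=config, cohort=cohort, features_raw=features_raw,
        features_corrected=features_corrected,
        features_normalized=features_normalized, behavior=behavior,
        behavior_truth=truth, scores=scores, icc=icc, comparison=comparison,
        edges=edges, model_performance=model_perf, model_tlx=model_tlx,
        rejection_rates=rejection, log=log,
    )
    if out_dir is not None:
        write_bundle(result, out_dir)
    return result


def write_bundle(result: RunResult, out_dir: str | Path) -> None:
    """Write the report bundle with deterministic formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for stage, table in (("raw", result.features_raw),
                         ("corrected", result.features_corrected),
                         ("normalized", result.features_normalized)):
        frame = table.values.copy()
        frame.insert(0, "group", table.groups)
        frame.to_csv(out / f"features_{stage}.tsv", sep="\t",
                     index_label="participant")

    result.behavior.to_csv(out / "behavior.csv")
    result.scores.to_csv(out / "scores.tsv", sep="\t")
    result.comparison.to_csv(out / "group_comparison.tsv", sep="\t",
                             index=False)
    render_comparison_table(result.comparison).to_csv(
        out / "significant_coherence.tsv", sep="\t", index=False)
    result.edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    (out / "model_performance.json").write_text(
        json.dumps(result.model_performance.to_dict(), indent=1,
                   sort_keys=True))
    (out / "model_tlx.json").write_text(
        json.dumps(result.model_tlx.to_dict(), indent=1, sort_keys=True))
    (out / "run_log.json").write_text(
        json.dumps(result.log, indent=1, sort_keys=True))
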