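"""Synthetic cohort generator: validation, determinism, ground truth."""

from dataclasses import replace

import numpy as np
import pytest

from examcoh.features import minmax_normalize
from examcoh.montage import CHANNELS
from examcoh.preprocess import (epoch_segment, preprocess_recording,
                                reject_artifacts, segment_tasks)
from examcoh.simulate import (DEFAULT_EFFECTS, BehaviorModel, CohortConfig,
                              Effect, inject_artifacts, simulate_behavior,
                              simulate_recording)
from examcoh.spectral import band_by_name, coherence_matrix


def _one_effect_config(gamma2, band="theta", seconds=180.0, seed=0):
    return CohortConfig(
        n_per_group=2,
        segment_plan=(("eyes open", 2.0), ("reading", seconds),
                      ("answer 1", 2.0), ("answer 2", 2.0)),
        effect_table=(Effect(("FC5", "FC6"), band, "reading",
                             gamma2, gamma2),),
        coupling_jitter_sd=0.0,
        artifact_rate=0.0,
        seed=seed,
    )


def _band_coherence(config, seed, pair=("FC5", "FC6"), band="theta",
                    group="experienced"):
    rec, _ = simulate_recording(replace(config, seed=seed), 0, group)
    bounds = segment_tasks(rec)
    es = epoch_segment(rec, bounds["reading"], task="reading")
    freqs, coh = coherence_matrix(es)
    i, j = CHANNELS.index(pair[0]), CHANNELS.index(pair[1])
    return coh[i, j, band_by_name(band).bins(freqs)].mean()


class TestConfigValidation:
    def test_defaults_valid(self):
        cfg = CohortConfig()
        assert cfg.total_duration == 1260.0
        assert len(cfg.effect_table) == len(DEFAULT_EFFECTS)

    @pytest.mark.parametrize("kwargs, match", [
        (dict(n_per_group=1), "n_per_group"),
        (dict(artifact_rate=1.0), "artifact_rate"),
        (dict(segment_plan=(("eyes open", -3.0),)), "duration"),
        (dict(segment_plan=(("coffee", 10.0),)), "unknown segment"),
    ])
    def test_bad_scalars_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            CohortConfig(**kwargs)

    def test_coherence_target_one_unattainable(self):
        with pytest.raises(ValueError, match="unattainable"):
            CohortConfig(effect_table=(
                Effect(("FC5", "FC6"), "theta", "reading", 1.0, 0.5),))

    def test_overlapping_effects_rejected(self):
        eff = Effect(("FC5", "FC6"), "theta", "reading", 0.1, 0.5)
        flipped = Effect(("FC6", "FC5"), "theta", "reading", 0.2, 0.4)
        with pytest.raises(ValueError, match="overlapping"):
            CohortConfig(effect_table=(eff, flipped))

    def test_pair_must_be_two_distinct_montage_channels(self):
        with pytest.raises(ValueError, match="distinct"):
            CohortConfig(effect_table=(
                Effect(("FC5", "FC5"), "theta", "reading", 0.1, 0.2),))
        with pytest.raises(KeyError):
            CohortConfig(effect_table=(
                Effect(("FC5", "Cz"), "theta", "reading", 0.1, 0.2),))


class TestSignalGeneration:
    def test_fixed_seed_is_bit_identical(self, small_cohort_config):
        a, ta = simulate_recording(small_cohort_config, 1, "novice")
        b, tb = simulate_recording(small_cohort_config, 1, "novice")
        assert np.array_equal(a.data, b.data)
        assert ta.coupling == tb.coupling
        c, _ = simulate_recording(small_cohort_config, 2, "novice")
        assert not np.array_equal(a.data, c.data)

    def test_all_samples_finite_and_markers_complete(self, demo_recording):
        assert np.isfinite(demo_recording.data).all()
        assert [m[0] for m in demo_recording.markers] == [
            "eyes open", "reading", "answer 1", "answer 2"]
        assert demo_recording.duration == 100.0

    def test_background_amplitude_scale(self, demo_recording):
        rms = demo_recording.data.std(axis=1)
        assert np.all(rms > 10.0) and np.all(rms < 45.0)

    def test_posterior_alpha_rhythm_present(self, small_cohort_config):
        from examcoh.spectral import band_power, psd_epochs

        rec, _ = simulate_recording(small_cohort_config, 0, "novice")
        es = epoch_segment(rec, segment_tasks(rec)["baseline"],
                           task="baseline")
        freqs, p = psd_epochs(es)
        alpha = band_power(p, freqs, band_by_name("alpha"))
        assert alpha[CHANNELS.index("O1")] > 1.5 * alpha[CHANNELS.index("AF3")]

    def test_closed_form_coherence_quarter(self):
        # symmetric mixing with theoretical band coherence 0.25
        cfg = _one_effect_config(0.25)
        vals = [_band_coherence(cfg, s) for s in range(5)]
        assert np.mean(vals) == pytest.approx(0.25, abs=0.02)

    def test_zero_coupling_floor(self):
        cfg = _one_effect_config(0.25)
        vals = [_band_coherence(cfg, s, pair=("AF3", "O2")) for s in range(5)]
        assert np.mean(vals) == pytest.approx(1.0 / 180.0, abs=0.004)

    def test_group_targets_differ_in_designed_direction(self):
        cfg = CohortConfig(
            n_per_group=2,
            segment_plan=(("eyes open", 2.0), ("reading", 120.0),
                          ("answer 1", 2.0), ("answer 2", 2.0)),
            effect_table=(Effect(("FC5", "FC6"), "theta", "reading",
                                 0.13, 0.52),),
            coupling_jitter_sd=0.0, artifact_rate=0.0, seed=5)
        exp = _band_coherence(cfg, 5, group="experienced")
        nov = _band_coherence(cfg, 5, group="novice")
        assert nov > exp + 0.2


class TestArtifacts:
    def test_rate_zero_identity(self, demo_recording):
        out, hit = inject_artifacts(demo_recording, 0.0, seed=1)
        assert hit == []
        assert np.array_equal(out.data, demo_recording.data)

    def test_contamination_count_matches_rate(self, demo_recording):
        out, hit = inject_artifacts(demo_recording, 0.10, seed=2)
        # 20 + 40 + 20 exam-task epochs -> 10% = 8
        assert len(hit) == round(0.10 * 80)
        assert len(set(hit)) == len(hit)
        for task, idx in hit:
            assert task in ("reading", "answer1", "answer2")

    def test_detector_sensitivity_on_injected_epochs(self, demo_recording):
        out, hit = inject_artifacts(demo_recording, 0.10, seed=3)
        by_task = {}
        bounds = segment_tasks(out)
        for task in ("reading", "answer1", "answer2"):
            es = epoch_segment(out, bounds[task], task=task)
            by_task[task] = reject_artifacts(es).artifact_mask
        caught = sum(bool(by_task[task][idx]) for task, idx in hit)
        assert caught / len(hit) >= 0.95

    def test_rate_one_rejected(self, demo_recording):
        with pytest.raises(ValueError):
            inject_artifacts(demo_recording, 1.0, seed=0)


class TestBehavior:
    @pytest.fixture()
    def feature_table(self, small_cohort_config):
        import pandas as pd
        from examcoh.features import FeatureTable

        rng = np.random.default_rng(0)
        pids = ["exp01", "exp02", "nov01", "nov02"]
        values = pd.DataFrame(
            rng.uniform(0, 1, (4, 5)),
            index=pids,
            columns=["answer1.beta.coh.F7-F8", "reading.theta.coh.FC5-FC6",
                     "answer1.theta.coh.F4-F8", "answer2.theta.coh.F7-AF4",
                     "answer2.alpha.psd.F3"])
        groups = pd.Series(["experienced", "experienced",
                            "novice", "novice"], index=pids)
        return FeatureTable(minmax_normalize(
            FeatureTable(values, groups, "raw")).values, groups, "normalized")

    def test_zero_noise_identity_link(self, small_cohort_config,
                                      feature_table):
        bm = BehaviorModel(performance_intercept=0.0,
                           performance_terms={
                               "answer1.beta.coh.F7-F8": 1.0},
                           noise_sd=0.0, rater_flip_prob=0.0)
        cfg = replace(small_cohort_config, behavior_model=bm)
        _, truth = simulate_behavior(cfg, feature_table, seed=1)
        assert np.allclose(truth.performance_true,
                           feature_table.values["answer1.beta.coh.F7-F8"])

    def test_zero_rater_noise_gives_perfect_agreement(
            self, small_cohort_config, feature_table):
        from examcoh.behavior import rater_agreement, score_behavior

        bm = BehaviorModel(rater_flip_prob=0.0)
        cfg = replace(small_cohort_config, behavior_model=bm)
        table, _ = simulate_behavior(cfg, feature_table, seed=2)
        icc = rater_agreement(score_behavior(table))
        assert icc.icc == pytest.approx(1.0)

    def test_unknown_feature_name_rejected(self, small_cohort_config,
                                           feature_table):
        bm = BehaviorModel(performance_terms={"reading.zeta.coh.XX-YY": 1.0})
        cfg = replace(small_cohort_config, behavior_model=bm)
        with pytest.raises(ValueError, match="unknown feature"):
            simulate_behavior(cfg, feature_table, seed=0)

    def test_outputs_within_instrument_ranges(self, small_cohort_config,
                                              feature_table):
        table, _ = simulate_behavior(small_cohort_config, feature_table,
                                     seed=3)
        tlx_cols = [c for c in table.columns if c.startswith("tlx_")]
        assert ((table[tlx_cols] >= 0) & (table[tlx_cols] <= 20)).all().all()
        item_cols = [c for c in table.columns if "_item" in c]
        assert table[item_cols].isin([0, 1, 2]).all().all()
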