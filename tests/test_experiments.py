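"""Experiment orchestration: splits, zero-shot, scenarios, summaries."""

from __future__ import annotations

import numpy as np
import pytest

import ethoseg as es
from ethoseg.experiments import (
    ExperimentResult,
    ExperimentSpec,
    SplitError,
    channel_norm,
    evaluate_model,
    predict_recording,
    run_scenario,
    run_zero_shot,
    split_individuals,
    summarize_matrix,
)
from ethoseg.nn.models import ArchitectureSpec, Scenario, build_model
from ethoseg.training import TrainConfig
from ethoseg.windows import WindowPlan


@pytest.fixture(scope="module")
def target_recs():
    cfg = es.StudyConfig(n_source=1, n_target=6, source_duration_s=60.0,
                         target_duration_s=240.0, master_seed=21)
    return [es.preprocess(r) for r in es.make_study_datasets(cfg).target]


def _tiny_arch() -> ArchitectureSpec:
    return ArchitectureSpec("vnet", 32, 7, 7, 2)


def _tiny_spec(scenario: Scenario, n_repeats: int = 2) -> ExperimentSpec:
    return ExperimentSpec(
        name=f"t-{scenario.value}", scenario=scenario, arch=_tiny_arch(),
        plan=WindowPlan(ws=32, n_train=64, n_val=32),
        train_config=TrainConfig(epochs=2, batch_size=16, learning_rate=1e-3),
        n_repeats=n_repeats, split_seed=3)


class TestSplits:
    def test_split_is_disjoint_by_individual(self, target_recs):
        tr, va, te = split_individuals(target_recs, 3, 1, 2, seed=0)
        ids = [r.individual_id for r in tr + va + te]
        assert len(set(ids)) == 6
        assert (len(tr), len(va), len(te)) == (3, 1, 2)

    def test_wrong_totals_rejected(self, target_recs):
        with pytest.raises(SplitError):
            split_individuals(target_recs, 3, 1, 1, seed=0)

    def test_split_deterministic_per_seed(self, target_recs):
        a = split_individuals(target_recs, 3, 1, 2, seed=5)
        b = split_individuals(target_recs, 3, 1, 2, seed=5)
        assert [r.individual_id for r in a[0]] == [r.individual_id for r in b[0]]


class TestPredictionPath:
    def test_track_length_equals_recording(self, target_recs):
        model = build_model(_tiny_arch(), seed=0)
        track = predict_recording(model, target_recs[0])
        assert track.probs.shape == (target_recs[0].n_samples, 7)
        assert np.allclose(track.probs.sum(axis=1), 1.0)

    def test_untrained_model_recall_near_chance(self, target_recs):
        """A random-weight model cannot beat chance-level macro recall."""
        model = build_model(_tiny_arch(), seed=1)
        model.set_input_norm(*channel_norm(target_recs))
        ev = evaluate_model(model, target_recs[:2])
        recalls = [v for c, v in ev["report"].recall.items()
                   if ev["report"].support[c] > 0]
        assert np.mean(recalls) < 40.0  # chance is ~14% for 7 classes

    def test_confusion_count_conservation(self, target_recs):
        model = build_model(_tiny_arch(), seed=2)
        ev = evaluate_model(model, target_recs[:2])
        n_labeled = sum(r.n_samples for r in target_recs[:2])
        assert ev["confusion"].total == n_labeled
        for budgets in ev["time_budgets"].values():
            assert sum(budgets["predicted"].values()) == pytest.approx(1.0)
            assert sum(budgets["observed"].values()) == pytest.approx(1.0)


class TestZeroShot:
    def test_no_training_and_audit_hash(self, target_recs):
        model = build_model(_tiny_arch(), seed=3)
        h0 = model.weights_hash()
        result = run_zero_shot(model, target_recs[:2])
        assert model.weights_hash() == h0
        assert result.source_weights_hash == h0
        assert len(result.runs) == 1


class TestRunScenario:
    def test_scratch_runs_and_aggregates(self, target_recs):
        result = run_scenario(_tiny_spec(Scenario.SCRATCH), target_recs,
                              master_seed=4)
        assert len(result.runs) == 2
        s = result.summary()
        assert s["n_runs"] == 2
        assert s["min_f1"] <= s["mean_f1"] <= s["max_f1"]
        assert set(result.split) == {"train", "val", "test"}

    def test_tl_requires_source_model(self, target_recs):
        with pytest.raises(ValueError):
            run_scenario(_tiny_spec(Scenario.TL_ALL), target_recs)

    def test_head_only_updates_only_head(self, target_recs):
        source = build_model(_tiny_arch(), seed=5)
        source.set_input_norm(*channel_norm(target_recs))
        spec = _tiny_spec(Scenario.TL_HEAD_ONLY, n_repeats=1)
        result = run_scenario(spec, target_recs, source_model=source,
                              master_seed=5)
        assert result.freeze_plan == {g: (g == "head") for g in source.groups}
        assert result.source_weights_hash == source.weights_hash()

    def test_deterministic_across_invocations(self, target_recs):
        source = build_model(_tiny_arch(), seed=6)
        source.set_input_norm(*channel_norm(target_recs))
        spec = _tiny_spec(Scenario.TL_ALL)
        r1 = run_scenario(spec, target_recs, source_model=source, master_seed=7)
        r2 = run_scenario(spec, target_recs, source_model=source, master_seed=7)
        assert [x["macro_f1"] for x in r1.runs] == [x["macro_f1"] for x in r2.runs]
        assert r1.runs[0]["confusion"] == r2.runs[0]["confusion"]

    def test_head_replacement_path_for_class_mismatch(self, target_recs):
        """A 6-class source model is adapted via head replacement before
        fine-tuning on the 7-class target ethogram."""
        arch6 = ArchitectureSpec("vnet", 32, 7, 6, 2)
        source = build_model(arch6, seed=8)
        source.set_input_norm(*channel_norm(target_recs))
        spec = _tiny_spec(Scenario.TL_ALL, n_repeats=1)
        result = run_scenario(spec, target_recs, source_model=source,
                              master_seed=8)
        assert len(result.runs) == 1


class TestCrossTaxon:
    def test_matrix_cross_taxon_arm_with_head_replacement(self, target_recs):
        """End-to-end cross-taxon transfer: a 6-channel 6-class U-Net
        pre-trained on the human-activity analogue is adapted to the
        7-class turtle target by head replacement and fine-tuned."""
        from ethoseg.experiments import MatrixConfig, run_matrix
        from ethoseg.synthetic import make_human_analog_recordings

        humans = [es.preprocess(r, include_pressure=False)
                  for r in make_human_analog_recordings(
                      n_individuals=4, duration_s=240.0, master_seed=13)]
        cfg = MatrixConfig(scenarios=(), include_zero_shot=False,
                           include_cross_taxon=True, n_repeats=1,
                           pretrain_epochs=1, finetune_epochs=1,
                           pretrain_windows=64, train_windows=64,
                           val_windows=32, ws=32, depth=2,
                           human_ws=32, human_depth=2)
        results, df = run_matrix(target_recs, target_recs, cfg,
                                 master_seed=13, human_recordings=humans)
        assert df.loc[0, "name"] == "unet-cross-taxon"
        assert len(results[0].runs) == 1
        assert results[0].source_weights_hash is not None


class TestSummaries:
    def _result(self, f1s, name="x") -> ExperimentResult:
        r = ExperimentResult(name=name, scenario=Scenario.SCRATCH)
        r.runs = [{"macro_f1": v} for v in f1s]
        return r

    def test_single_run_has_no_sd(self):
        df = summarize_matrix([self._result([42.0])])
        assert df.loc[0, "mean_f1"] == 42.0
        assert df.loc[0, "sd_f1"] is None or np.isnan(df.loc[0, "sd_f1"])

    def test_constant_runs_have_zero_sd(self):
        df = summarize_matrix([self._result([10.0, 10.0, 10.0])])
        assert df.loc[0, "sd_f1"] == 0.0

    def test_summary_matches_independent_recomputation(self, rng):
        f1s = rng.uniform(0, 100, 9).tolist()
        df = summarize_matrix([self._result(f1s)])
        assert df.loc[0, "mean_f1"] == pytest.approx(np.mean(f1s))
        assert df.loc[0, "sd_f1"] == pytest.approx(np.std(f1s, ddof=1))
        assert df.loc[0, "min_f1"] == pytest.approx(min(f1s))
        assert df.loc[0, "max_f1"] == pytest.approx(max(f1s))
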