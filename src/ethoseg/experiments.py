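"""Cross-species transfer-learning experiment matrix.

Orchestrates the study design end-to-end on the synthetic species pair:
pre-train on the data-rich source species, then compare on the data-poor
target species (split by individual into train/validation/test)

* zero-shot application of the source model (no fine-tuning),
* a scratch baseline trained from random initialization,
* four transfer scenarios (fine-tune all, freeze encoder, freeze decoder,
  head only), each repeated with run-derived seeds,
* optionally a cross-taxon arm: a U-Net pre-trained on a six-channel
  six-class analogue dataset, adapted by head replacement.

All metrics are computed on reassembled full-length tracks of the held-out
test individuals, never on isolated windows.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import (
    ConfusionMatrix,
    MetricsReport,
    PredictionTrack,
    confusion,
    metrics_from_confusion,
    time_budget,
)
from .nn.models import (
    ArchitectureSpec,
    FreezePlan,
    Scenario,
    SegModel,
    apply_freeze_plan,
    build_model,
    clone_model,
    replace_head,
)
from .records import PreprocessedRecording
from .training import RunRecord, TrainConfig, train
from .windows import (
    WindowPlan,
    generate_balanced_windows,
    reassemble_predictions,
    segment_test_windows,
)

logger = logging.getLogger(__name__)


class SplitError(ValueError):
    """Train/validation/test individuals are not disjoint or do not add up."""


def split_individuals(recordings: list[PreprocessedRecording], n_train: int,
                      n_val: int, n_test: int, seed: int
                      ) -> tuple[list[PreprocessedRecording], ...]:
    """Deterministic random split by individual (never by window)."""
    if n_train + n_val + n_test != len(recordings):
        raise SplitError(
            f"split {n_train}/{n_val}/{n_test} != {len(recordings)} individuals")
    order = np.random.default_rng(seed).permutation(len(recordings))
    train_r = [recordings[i] for i in order[:n_train]]
    val_r = [recordings[i] for i in order[n_train:n_train + n_val]]
    test_r = [recordings[i] for i in order[n_train + n_val:]]
    ids = [r.individual_id for r in train_r + val_r + test_r]
    if len(set(ids)) != len(ids):
        raise SplitError("an individual appears in more than one split")
    return train_r, val_r, test_r


def _match_channels(rec: PreprocessedRecording, nb_desc: int
                    ) -> PreprocessedRecording:
    """Trim the channel matrix to the first ``nb_desc`` channels (e.g. drop
    the pressure channel when feeding turtle data to the 6-channel U-Net)."""
    if rec.nb_desc == nb_desc:
        return rec
    if rec.nb_desc < nb_desc:
        raise ValueError(f"recording has {rec.nb_desc} channels, need {nb_desc}")
    return PreprocessedRecording(
        individual_id=rec.individual_id, X=rec.X[:nb_desc], y=rec.y,
        cuts=rec.cuts, sample_rate=rec.sample_rate,
        channel_names=rec.channel_names[:nb_desc])


def channel_norm(recordings: list[PreprocessedRecording]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and s.d. pooled over recordings (training split only);
    fixed into the model so the same standardization follows the weights."""
    X = np.concatenate([r.X for r in recordings], axis=1)
    return X.mean(axis=1), X.std(axis=1)


def predict_recording(model: SegModel, rec: PreprocessedRecording,
                      overlap_fraction: float = 0.1,
                      batch_size: int = 64) -> PredictionTrack:
    """Segment -> predict -> reassemble one full recording."""
    rec = _match_channels(rec, model.spec.nb_desc)
    batch, starts = segment_test_windows(rec, model.spec.ws, overlap_fraction,
                                         n_classes=model.spec.nb_behaviors)
    probs = np.empty((len(batch), model.spec.ws, model.spec.nb_behaviors))
    for i in range(0, len(batch), batch_size):
        probs[i:i + batch_size] = model.predict_proba(batch.inputs[i:i + batch_size])
    track = reassemble_predictions(probs, starts, rec.n_samples)
    return PredictionTrack(probs=track, individual_id=rec.individual_id)


def evaluate_model(model: SegModel, recordings: list[PreprocessedRecording],
                   overlap_fraction: float = 0.1) -> dict:
    """Reassembled-track evaluation over a set of individuals.

    Returns the pooled confusion matrix and metrics plus per-individual
    predicted and observed time budgets.
    """
    classes = tuple(range(model.spec.nb_behaviors))
    total = np.zeros((len(classes), len(classes)), dtype=np.int64)
    budgets = {}
    for rec in recordings:
        track = predict_recording(model, rec, overlap_fraction)
        cm = confusion(rec.y, track.labels, classes)
        total += cm.counts
        budgets[rec.individual_id] = {
            "predicted": time_budget(track.labels, classes),
            "observed": time_budget(rec.y, classes),
        }
    cm_all = ConfusionMatrix(counts=total, classes=classes)
    return {"report": metrics_from_confusion(cm_all), "confusion": cm_all,
            "time_budgets": budgets}


@dataclass
class ExperimentSpec:
    """One arm of the experiment matrix."""

    name: str
    scenario: Scenario
    arch: ArchitectureSpec
    plan: WindowPlan
    train_config: TrainConfig
    n_repeats: int = 5
    split_seed: int = 0
    n_train_ind: int = 3
    n_val_ind: int = 1
    n_test_ind: int = 2


@dataclass
class ExperimentResult:
    """Per-run metrics plus the audit trail of what was actually applied."""

    name: str
    scenario: Scenario | None  # None = zero-shot (no training)
    runs: list[dict] = field(default_factory=list)
    freeze_plan: dict[str, bool] = field(default_factory=dict)
    source_weights_hash: str | None = None
    split: dict[str, list[str]] = field(default_factory=dict)

    @property
    def f1_values(self) -> np.ndarray:
        return np.array([r["macro_f1"] for r in self.runs])

    def summary(self) -> dict:
        f1 = self.f1_values
        scenario = self.scenario.value if self.scenario is not None else "none"
        out = {"name": self.name, "scenario": scenario,
               "n_runs": len(f1), "mean_f1": float(f1.mean()),
               "min_f1": float(f1.min()), "max_f1": float(f1.max())}
        out["sd_f1"] = float(f1.std(ddof=1)) if len(f1) > 1 else None
        return out


def _run_seeds(master_seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence([master_seed, 7919]).spawn(n)]


def run_zero_shot(source_model: SegModel,
                  target_recordings: list[PreprocessedRecording],
                  overlap_fraction: float = 0.1,
                  name: str = "zero-shot") -> ExperimentResult:
    """Apply a source-species model to target individuals with no training."""
    ev = evaluate_model(source_model, target_recordings, overlap_fraction)
    result = ExperimentResult(
        name=name, scenario=None,
        source_weights_hash=source_model.weights_hash(),
        split={"test": [r.individual_id for r in target_recordings]})
    result.runs.append(_run_entry(ev, seed=None, record=None))
    return result


def _run_entry(ev: dict, seed: int | None, record: RunRecord | None) -> dict:
    report: MetricsReport = ev["report"]
    entry = {
        "macro_f1": report.macro_f1, "accuracy": report.accuracy,
        "ovr_accuracy": report.ovr_accuracy, "weighted_f1": report.weighted_f1,
        "per_class_f1": dict(report.f1), "per_class_precision": dict(report.precision),
        "per_class_recall": dict(report.recall),
        "confusion": ev["confusion"].counts.tolist(),
        "time_budgets": ev["time_budgets"], "seed": seed,
    }
    if record is not None:
        entry["best_epoch"] = record.best_epoch
        entry["val_metric"] = list(record.val_metric)
        entry["wall_time_s"] = record.wall_time_s
    return entry


def run_scenario(spec: ExperimentSpec,
                 target_recordings: list[PreprocessedRecording],
                 source_model: SegModel | None = None,
                 master_seed: int = 0) -> ExperimentResult:
    """Run one experiment arm: build/load, freeze, train n_repeats times,
    evaluate each run on the held-out test individuals, aggregate."""
    if spec.scenario is not Scenario.SCRATCH and source_model is None:
        raise ValueError(f"{spec.scenario} requires a source model")

    train_r, val_r, test_r = split_individuals(
        target_recordings, spec.n_train_ind, spec.n_val_ind, spec.n_test_ind,
        spec.split_seed)
    train_r = [_match_channels(r, spec.arch.nb_desc) for r in train_r]
    val_r = [_match_channels(r, spec.arch.nb_desc) for r in val_r]

    result = ExperimentResult(
        name=spec.name, scenario=spec.scenario,
        source_weights_hash=(source_model.weights_hash()
                             if source_model is not None else None),
        split={"train": [r.individual_id for r in train_r],
               "val": [r.individual_id for r in val_r],
               "test": [r.individual_id for r in test_r]})

    n_classes = spec.arch.nb_behaviors
    val_batch = generate_balanced_windows(
        val_r, spec.plan, rng_seed=spec.split_seed + 1,
        n_windows=spec.plan.n_val, n_classes=n_classes)

    for seed in _run_seeds(master_seed, spec.n_repeats):
        if spec.scenario is Scenario.SCRATCH:
            model = build_model(spec.arch, seed=seed)
            model.set_input_norm(*channel_norm(train_r))
        elif source_model.spec.nb_behaviors != n_classes:
            model = replace_head(source_model, n_classes, seed=seed)
        else:
            model = clone_model(source_model, seed=seed)
        plan = FreezePlan.for_model(spec.scenario, model)
        apply_freeze_plan(model, plan)
        result.freeze_plan = dict(plan.trainable)

        def train_source(epoch: int, _seed: int = seed) -> "object":
            epoch_seed = np.random.SeedSequence([_seed, epoch])
            return generate_balanced_windows(
                train_r, spec.plan, rng_seed=np.random.default_rng(epoch_seed),
                n_windows=spec.plan.n_train, n_classes=n_classes)

        cfg = dataclasses.replace(spec.train_config, seed=seed)
        model, record = train(model, train_source, val_batch, cfg)
        ev = evaluate_model(model, test_r, spec.plan.overlap_fraction)
        result.runs.append(_run_entry(ev, seed=seed, record=record))
        logger.info("%s seed=%d macro F1=%.2f%%", spec.name, seed,
                    result.runs[-1]["macro_f1"])
    return result


def summarize_matrix(results: list[ExperimentResult]) -> pd.DataFrame:
    """Per-experiment mean/s.d./min/max F1 as a machine-readable table."""
    if not results:
        raise ValueError("need at least one result")
    rows = [r.summary() for r in results]
    df = pd.DataFrame(rows, columns=["name", "scenario", "n_runs", "mean_f1",
                                     "sd_f1", "min_f1", "max_f1"])
    return df


# ---------------------------------------------------------------------------
# desk-scale matrix
# ---------------------------------------------------------------------------

@dataclass
class MatrixConfig:
    """Desk-scale settings for the full experiment grid.

    The architecture is shrunk (ws=64, depth=8) and epochs/window counts
    reduced so the whole grid runs on one CPU; the experimental *design*
    (13/6 individuals, 3/1/2 target split, balanced windows, 10% overlap,
    best-on-validation checkpointing, repeated seeded runs) is unchanged.
    """

    ws: int = 64
    depth: int = 8
    overlap_fraction: float = 0.1
    train_windows: int = 600
    val_windows: int = 300
    pretrain_windows: int = 1500
    pretrain_epochs: int = 30
    finetune_epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 32
    n_repeats: int = 5
    scenarios: tuple[Scenario, ...] = (
        Scenario.SCRATCH, Scenario.TL_ALL, Scenario.TL_FREEZE_ENCODER,
        Scenario.TL_FREEZE_DECODER, Scenario.TL_HEAD_ONLY)
    include_zero_shot: bool = True
    include_cross_taxon: bool = False
    human_ws: int = 32
    human_depth: int = 4

    def plan(self) -> WindowPlan:
        return WindowPlan(ws=self.ws, overlap_fraction=self.overlap_fraction,
                          n_train=self.train_windows, n_val=self.val_windows)


def pretrain_source_model(source_recordings: list[PreprocessedRecording],
                          cfg: MatrixConfig, master_seed: int = 0,
                          family: str = "vnet", nb_desc: int | None = None,
                          nb_behaviors: int = 7, ws: int | None = None,
                          depth: int | None = None, loss: str = "gdl",
                          n_candidates: int = 3) -> tuple[SegModel, RunRecord]:
    """Train the source-species model (7/3/3 split by individual).

    ``n_candidates`` initializations are trained and the one with the best
    *source-validation* macro F1 is kept: the pre-trained model plays the
    role of a published, vetted artifact, so it is selected on its own
    species' validation data (target data is never consulted).
    """
    nb_desc = nb_desc or source_recordings[0].nb_desc
    ws = ws or cfg.ws
    depth = depth or cfg.depth
    n = len(source_recordings)
    n_val = max(1, round(n * 3 / 13))
    n_test = max(1, round(n * 3 / 13))
    train_r, val_r, _ = split_individuals(
        source_recordings, n - n_val - n_test, n_val, n_test, seed=master_seed)
    arch = ArchitectureSpec(family=family, ws=ws, nb_desc=nb_desc,
                            nb_behaviors=nb_behaviors, depth=depth)
    plan = WindowPlan(ws=ws, overlap_fraction=cfg.overlap_fraction,
                      n_train=cfg.pretrain_windows, n_val=cfg.val_windows)
    val_batch = generate_balanced_windows(val_r, plan, rng_seed=master_seed + 1,
                                          n_windows=plan.n_val,
                                          n_classes=nb_behaviors)
    norm = channel_norm(train_r)
    cand_seeds = [int(s.generate_state(1)[0] % (2**31))
                  for s in np.random.SeedSequence([master_seed, 15485863]
                                                  ).spawn(n_candidates)]
    best: tuple[SegModel, RunRecord] | None = None
    for cand_seed in cand_seeds:
        model = build_model(arch, seed=cand_seed)
        model.set_input_norm(*norm)

        def train_source(epoch: int, _seed: int = cand_seed) -> "object":
            seq = np.random.SeedSequence([_seed, 104729, epoch])
            return generate_balanced_windows(train_r, plan,
                                             rng_seed=np.random.default_rng(seq),
                                             n_windows=plan.n_train,
                                             n_classes=nb_behaviors)

        tc = TrainConfig(epochs=cfg.pretrain_epochs, batch_size=cfg.batch_size,
                         learning_rate=cfg.learning_rate, loss=loss,
                         seed=cand_seed)
        model, record = train(model, train_source, val_batch, tc)
        logger.info("pretrain candidate seed=%d source-val F1=%.2f%%",
                    cand_seed, record.best_val_metric)
        if best is None or record.best_val_metric > best[1].best_val_metric:
            best = (model, record)
    return best


def run_matrix(source_recordings: list[PreprocessedRecording],
               target_recordings: list[PreprocessedRecording],
               cfg: MatrixConfig | None = None, master_seed: int = 0,
               human_recordings: list[PreprocessedRecording] | None = None
               ) -> tuple[list[ExperimentResult], pd.DataFrame]:
    """Run the full grid and return (results, summary table)."""
    cfg = cfg or MatrixConfig()
    source_model, _ = pretrain_source_model(source_recordings, cfg,
                                            master_seed=master_seed)
    results: list[ExperimentResult] = []
    if cfg.include_zero_shot:
        results.append(run_zero_shot(source_model, target_recordings,
                                     cfg.overlap_fraction))

    ft = TrainConfig(epochs=cfg.finetune_epochs, batch_size=cfg.batch_size,
                     learning_rate=cfg.learning_rate, loss="gdl")
    for scenario in cfg.scenarios:
        spec = ExperimentSpec(
            name=f"vnet-{scenario.value}", scenario=scenario,
            arch=source_model.spec, plan=cfg.plan(), train_config=ft,
            n_repeats=cfg.n_repeats, split_seed=master_seed)
        results.append(run_scenario(
            spec, target_recordings,
            source_model=None if scenario is Scenario.SCRATCH else source_model,
            master_seed=master_seed))

    if cfg.include_cross_taxon:
        if human_recordings is None:
            raise ValueError("cross-taxon arm requires human_recordings")
        human_model, _ = pretrain_source_model(
            human_recordings, cfg, master_seed=master_seed + 1, family="unet",
            nb_desc=6, nb_behaviors=6, ws=cfg.human_ws, depth=cfg.human_depth,
            loss="xent")
        arch7 = ArchitectureSpec(family="unet", ws=cfg.human_ws, nb_desc=6,
                                 nb_behaviors=7, depth=cfg.human_depth)
        plan = WindowPlan(ws=cfg.human_ws, overlap_fraction=cfg.overlap_fraction,
                          n_train=cfg.train_windows, n_val=cfg.val_windows)
        spec = ExperimentSpec(
            name="unet-cross-taxon", scenario=Scenario.TL_ALL, arch=arch7,
            plan=plan,
            train_config=dataclasses.replace(ft, loss="xent"),
            n_repeats=cfg.n_repeats, split_seed=master_seed)
        results.append(run_scenario(spec, target_recordings,
                                    source_model=human_model,
                                    master_seed=master_seed))

    return results, summarize_matrix(results)


def write_summary(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
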