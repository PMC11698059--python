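"""Ethogram time budgets: predicted vs observed for a held-out individual.

Pre-trains the desk-scale source model, fine-tunes all layers on the target
species' training individuals, then predicts every timestep of a held-out
test individual by overlapped-window reassembly and prints the share of
time the model assigns to each behavior next to the share in the
(synthetic) annotation.  Per-behavior agreement is what a field ecologist
would use to judge whether model-derived activity budgets are trustworthy.
The failure modes are as instructive as the agreement: with minutes of
fine-tuning data, signal-alike classes can swap wholesale (here the bursty
"feeding" bouts are labeled as the bursty, balance-oversampled "other"
class), which a budget comparison exposes immediately while a single
accuracy number would hide it.
"""

import numpy as np

import ethoseg as es
from ethoseg.behaviors import Behavior
from ethoseg.experiments import (
    MatrixConfig,
    predict_recording,
    pretrain_source_model,
    split_individuals,
)
from ethoseg.nn.models import FreezePlan, Scenario, apply_freeze_plan, clone_model
from ethoseg.training import TrainConfig, train
from ethoseg.windows import generate_balanced_windows

ds = es.make_study_datasets(es.StudyConfig(master_seed=0))
source = [es.preprocess(r) for r in ds.source]
target = [es.preprocess(r) for r in ds.target]

cfg = MatrixConfig()
source_model, record = pretrain_source_model(source, cfg, master_seed=0)
print(f"source model: best source-validation macro F1 "
      f"{record.best_val_metric:.1f}% at epoch {record.best_epoch}")

train_r, val_r, test_r = split_individuals(target, 3, 1, 2, seed=0)
model = clone_model(source_model)
apply_freeze_plan(model, FreezePlan.for_model(Scenario.TL_ALL, model))
plan = cfg.plan()
val_batch = generate_balanced_windows(val_r, plan, rng_seed=1,
                                      n_windows=plan.n_val, n_classes=7)
model, ft = train(
    model,
    lambda epoch: generate_balanced_windows(
        train_r, plan, rng_seed=np.random.default_rng([7, epoch]),
        n_windows=plan.n_train, n_classes=7),
    val_batch,
    TrainConfig(epochs=cfg.finetune_epochs, batch_size=cfg.batch_size,
                learning_rate=cfg.learning_rate, loss="gdl", seed=0))
print(f"fine-tuned:   best target-validation macro F1 "
      f"{ft.best_val_metric:.1f}% at epoch {ft.best_epoch}\n")

rec = test_r[0]
track = predict_recording(model, rec)
predicted = es.time_budget(track.labels, range(7))
observed = es.time_budget(rec.y, range(7))

print(f"time budget for held-out {rec.individual_id} "
      f"({rec.n_samples / 20 / 60:.1f} min labeled):")
print(f"{'behavior':<12}{'observed':>10}{'predicted':>11}")
for code in range(7):
    print(f"{Behavior(code).name:<12}{100 * observed[code]:>9.1f}%"
          f"{100 * predicted[code]:>10.1f}%")
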