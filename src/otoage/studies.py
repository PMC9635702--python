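"""Canned desk-scale experiments tying the pipeline together.

The recovery study is the package's standard end-to-end exercise: generate a
synthetic population whose morphology strongly encodes age (600 images,
64 x 64, ages 1-16, male/female mean ages 6 and 10 yr), hold out test and
validation folds by age-stratified allocation, train the tiny CNN with
augmentation, early stopping and the black-baseline training device, and
compare against the group-mean predictor (the model with zeroed head weights
and biases at the per-group mean ages).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .attribution import add_baseline_class
from .evaluation import PredictionSet, make_fold_plan, stratified_split
from .model import AgeRegressor, ModelConfig, TrainingHistory, build_model, \
    train_with_early_stopping
from .pipeline import AugmentSpec, DatasetTable
from .synthetic import sample_population, tiny_study_config


@dataclasses.dataclass
class RecoveryStudyResult:
    model: AgeRegressor
    history: TrainingHistory
    train: DatasetTable
    val: DatasetTable
    test: DatasetTable
    predictions: PredictionSet
    rmse: float
    baseline_rmse: float
    mean_pred_by_sex: dict
    configured_means: dict
    black_input_prediction: float


def group_mean_model(config: ModelConfig, bias: tuple[float, float, float],
                     seed: int = 0) -> AgeRegressor:
    """The per-sex-mean predictor: zero head weights, biases at group means."""
    cfg = dataclasses.replace(config, output_bias_init=bias)
    model = build_model(cfg, seed=seed)
    model.head.w.value[...] = 0.0
    return model


def _group_means(table: DatasetTable) -> tuple[float, float, float]:
    means = []
    for sex in ("male", "female", "unknown"):
        mask = np.array([s == sex for s in table.sex])
        means.append(float(table.read_ages[mask].mean()) if mask.any()
                     else float(table.read_ages.mean()))
    return tuple(means)


def run_recovery_study(seed: int = 0, n_total: int = 600,
                       max_epochs: int = 100, patience: int = 20,
                       n_baseline_images: int = 50,
                       k: int = 5) -> RecoveryStudyResult:
    """Generate, split, train and score the desk-scale study.

    Fold 1 of a k-fold age-stratified split is the test set, fold 2 the
    validation set; the remaining folds plus all unknown-sex fish plus
    ``n_baseline_images`` black age-0 images form the training set.
    """
    config = tiny_study_config(n_total=n_total, seed=seed)
    records = sample_population(config)
    table = DatasetTable.from_records(records)

    assignment = stratified_split(table, k=k, seed=seed)
    trial = make_fold_plan(assignment).trials[0]
    id_to_pos = {sid: i for i, sid in enumerate(table.sample_ids)}

    def sub(ids):
        return table.subset(np.array([id_to_pos[s] for s in ids], dtype=int))

    train, val, test = sub(trial.train_ids), sub(trial.val_ids), sub(trial.test_ids)
    if n_baseline_images > 0:
        train = add_baseline_class(train, n=n_baseline_images, seed=seed)

    bias = _group_means(train)
    model_config = ModelConfig(input_side=config.render.canvas_size,
                               output_bias_init=bias)
    model = build_model(model_config, seed=seed)
    model, history = train_with_early_stopping(
        model, train, val, augment_spec=AugmentSpec(), patience=patience,
        max_epochs=max_epochs, seed=seed)

    preds = model.predict(test.images, test.sex_codes)
    pred_set = PredictionSet.from_arrays(test.sample_ids, test.read_ages,
                                         preds, test.sex, trial=1)
    rmse = float(np.sqrt(np.mean((test.read_ages - preds) ** 2)))

    baseline = group_mean_model(model_config, bias, seed=seed)
    bpreds = baseline.predict(test.images, test.sex_codes)
    baseline_rmse = float(np.sqrt(np.mean((test.read_ages - bpreds) ** 2)))

    mean_pred_by_sex = {}
    for sex in ("male", "female"):
        mask = np.array([s == sex for s in test.sex])
        if mask.any():
            mean_pred_by_sex[sex] = float(preds[mask].mean())
    configured_means = {"male": config.age_means[0],
                        "female": config.age_means[1]}

    black = np.zeros_like(test.images[0])
    black_pred = float(model.predict(black[None],
                                     np.array([[1.0, 0.0, 0.0]]))[0])

    return RecoveryStudyResult(
        model=model, history=history, train=train, val=val, test=test,
        predictions=pred_set, rmse=rmse, baseline_rmse=baseline_rmse,
        mean_pred_by_sex=mean_pred_by_sex, configured_means=configured_means,
        black_input_prediction=black_pred)
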