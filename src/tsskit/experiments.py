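"""Experiment harnesses: class-ratio study, training-fraction study, and
cross-species generalization, each repeated over seeds.

Chromosome-holdout splits rule out classical k-fold cross-validation, so
"five-fold" evaluation is realized as five seeded repetitions: neural models
are re-initialized and re-shuffled, cascade SVMs re-randomize their level-0
subsets. The test partition is never resampled or reweighted — the ratio
study trains one arm at 1:10 and one arm undersampled to 1:1, but both are
evaluated on the untouched 1:10 test partition, which is the ratio found in
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cascade import (
    CascadeConfig,
    CascadeModel,
    fit_calibration,
    predict_proba as svm_predict_proba,
    train_cascade,
)
from .dataset import DatasetSplit, LabeledDataset, undersample_majority
from .errors import ConfigurationError, ContractError
from .metrics import EvalReport, evaluate
from .nn import TrainingConfig, build_architecture, predict_proba as nn_predict_proba, train

METRIC_COLUMNS = ["accuracy", "bc", "f1", "auc_roc"]


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str = "ratio"  # ratio | fraction | cross_species
    n_repeats: int = 5
    base_seed: int = 0
    fractions: tuple = (0.10, 0.50, 1.00)

    def validate(self) -> None:
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ConfigurationError("fractions must lie in (0, 1]")


@dataclass
class ExperimentReport:
    """Per-(classifier, cell, repeat) rows plus recomputable aggregates."""

    rows: pd.DataFrame

    def aggregate(self, by=("classifier", "cell", "partition")) -> pd.DataFrame:
        return (
            self.rows.groupby(list(by))[METRIC_COLUMNS]
            .agg(["mean", "std"])
            .reset_index()
        )


class CascadeSVMClassifier:
    """Cascade-SVM adapter for the experiment harness."""

    def __init__(self, config: CascadeConfig = CascadeConfig(), name: str | None = None):
        self.config = config
        self.name = name or f"svm_{config.kernel.name}"
        self.model: CascadeModel | None = None

    def fit(self, train: LabeledDataset, validation: LabeledDataset, seed: int):
        config = replace(self.config, seed=seed)
        self.model = train_cascade(train.sequences(), train.labels(), config)
        if len(validation):
            fit_calibration(self.model, validation.sequences(), validation.labels())
        return self

    def predict_proba(self, dataset: LabeledDataset) -> np.ndarray:
        return svm_predict_proba(self.model, dataset.sequences())

    @property
    def input_length(self) -> int | None:
        if self.model is None or not self.model.support_instances:
            return None
        first = self.model.support_instances[0]
        return len(first) if isinstance(first, str) else None


class NeuralClassifier:
    """Neural-architecture adapter for the experiment harness."""

    def __init__(self, architecture: str, input_length: int, training: TrainingConfig = TrainingConfig()):
        self.architecture = architecture
        self.name = architecture
        self._input_length = input_length
        self.training = training
        self.network = None
        self.history = None

    def fit(self, train_data: LabeledDataset, validation: LabeledDataset, seed: int):
        _, self.network = build_architecture(self.architecture, self._input_length, seed=seed)
        split = DatasetSplit(
            train=train_data,
            validation=validation,
            test=LabeledDataset([]),
            validation_chromosomes=frozenset(),
            test_chromosomes=frozenset(),
        )
        self.history = train(self.network, split, replace(self.training, seed=seed))
        return self

    def predict_proba(self, dataset: LabeledDataset) -> np.ndarray:
        return nn_predict_proba(self.network, dataset.sequences())

    @property
    def input_length(self) -> int:
        return self._input_length


def _evaluate_partitions(classifier, partitions: dict[str, LabeledDataset]) -> dict[str, EvalReport]:
    return {
        part: evaluate(ds.labels(), classifier.predict_proba(ds))
        for part, ds in partitions.items()
        if len(ds)
    }


def _rows_from_reports(classifier_name, cell, repeat, seed, reports) -> list[dict]:
    rows = []
    for partition, report in reports.items():
        d = report.to_dict()
        rows.append(
            {
                "classifier": classifier_name,
                "cell": cell,
                "repeat": repeat,
                "seed": seed,
                "partition": partition,
                "accuracy": d["accuracy"],
                "bc": d["bc"],
                "f1": d["f1"],
                "auc_roc": d["auc_roc"],
                "n": d["n"],
                "n_positive": d["n_positive"],
            }
        )
    return rows


def run_ratio_experiment(
    split: DatasetSplit,
    classifier_factories: dict,
    config: ExperimentConfig = ExperimentConfig(experiment="ratio"),
    oversampler=None,
) -> ExperimentReport:
    """Class-ratio study: train at 1:10 vs undersampled 1:1, test at 1:10.

    ``classifier_factories`` maps a name to a zero-argument factory returning
    a fresh classifier adapter. ``oversampler``, if given, is an external
    hook called as ``oversampler(train_dataset, seed) -> LabeledDataset``
    (e.g. a SMOTE wrapper) and adds a third arm.
    """
    config.validate()
    if len(split.train) == 0 or len(split.test) == 0:
        raise ConfigurationError("split must have non-empty train and test partitions")
    arms = {"1:10": lambda ds, seed: ds, "1:1-undersample": lambda ds, seed: undersample_majority(ds, 1.0, seed)}
    if oversampler is not None:
        arms["oversample"] = oversampler
    rows = []
    for name, factory in classifier_factories.items():
        for arm_name, make_train in arms.items():
            for repeat in range(config.n_repeats):
                seed = config.base_seed + repeat
                train_ds = make_train(split.train, seed)
                clf = factory().fit(train_ds, split.validation, seed)
                reports = _evaluate_partitions(clf, {"train": train_ds, "test": split.test})
                rows.extend(_rows_from_reports(name, arm_name, repeat, seed, reports))
    return ExperimentReport(pd.DataFrame(rows))


def stratified_fraction(
    dataset: LabeledDataset, fraction: float, seed: int
) -> LabeledDataset:
    """Stratified subset of size floor(fraction * n), nested across fractions.

    For a fixed seed each class's indices are shuffled once and the first
    floor(fraction * n_class) taken, so the 10% subset is contained in the
    50% subset drawn with the same seed.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return LabeledDataset(list(dataset.instances), dict(dataset.provenance))
    labels = dataset.labels()
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_take = int(np.floor(fraction * len(idx)))
        if n_take < 1:
            raise ConfigurationError(
                f"fraction {fraction} leaves no instances of class {cls}"
            )
        keep.extend(rng.permutation(idx)[:n_take].tolist())
    keep = sorted(keep)
    prov = dict(dataset.provenance)
    prov["fraction"] = fraction
    return LabeledDataset([dataset.instances[i] for i in keep], prov)


def run_fraction_experiment(
    split: DatasetSplit,
    classifier_factories: dict,
    fractions=(0.10, 0.50, 1.00),
    config: ExperimentConfig = ExperimentConfig(experiment="fraction"),
) -> ExperimentReport:
    """Training-data fraction study on stratified train subsets."""
    config.validate()
    rows = []
    for name, factory in classifier_factories.items():
        for fraction in fractions:
            for repeat in range(config.n_repeats):
                seed = config.base_seed + repeat
                train_ds = stratified_fraction(split.train, fraction, seed)
                clf = factory().fit(train_ds, split.validation, seed)
                reports = _evaluate_partitions(clf, {"train": train_ds, "test": split.test})
                rows.extend(_rows_from_reports(name, f"{fraction:.2f}", repeat, seed, reports))
    return ExperimentReport(pd.DataFrame(rows))


def run_cross_species(classifier, dataset_b: LabeledDataset) -> EvalReport:
    """Evaluate an already-fitted classifier on another species' dataset.

    No retraining happens; window lengths must match the model input.
    """
    if len(dataset_b) == 0:
        raise ConfigurationError("target dataset is empty")
    expected = getattr(classifier, "input_length", None)
    actual = len(dataset_b.instances[0].sequence)
    if expected is not None and actual != expected:
        raise ContractError(
            f"window length {actual} does not match model input length {expected}"
        )
    return evaluate(dataset_b.labels(), classifier.predict_proba(dataset_b))


def repeat_with_seeds(task, n_repeats: int = 5, base_seed: int = 0):
    """Run ``task(seed)`` for seeds base, base+1, ...; return the result list."""
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    return [task(base_seed + i) for i in range(n_repeats)]


def aggregate_results(values) -> dict:
    """Mean and standard deviation over repeated-seed scalar results."""
    arr = np.asarray(values, dtype=np.float64)
    return {"mean": float(arr.mean()), "std": float(arr.std(ddof=0)), "n": len(arr)}
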