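"""Cascade training for kernel SVMs (weighted-degree string and RBF kernels).

Training a kernel SVM on a large genomic dataset is dominated by the gram
matrix (quadratic in n). The cascade scheme makes it tractable: the training
set is split into 2^p random (stratified) subsets, an SVM is fitted on each
and only its support vectors are kept; adjacent support-vector sets are merged
pairwise and refitted up a binary tree until a single SVM remains. The final
support-vector set is then fed back into each level-0 subset and the whole
pass repeats until the global support set stabilizes (or a pass budget runs
out). With one subset the scheme degenerates to a single SVM fit.

Each node is fitted with scikit-learn's SVC on a precomputed gram sub-matrix,
so the full train gram is computed once per kernel and sliced per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from . import metrics as _metrics
from .encoding import flatten_batch
from .errors import ConfigurationError, ContractError, TrainingError
from .kernels import (
    RBFKernelParams,
    WDKernelParams,
    rbf_gram,
    wd_gram,
)


class WDKernel:
    """Weighted-degree kernel adapter: instances are equal-length strings."""

    name = "wd"

    def __init__(self, params: WDKernelParams = WDKernelParams()):
        self.params = params

    def gram(self, rows, cols=None) -> np.ndarray:
        return wd_gram(rows, cols, self.params)

    def validate_instances(self, instances, reference=None) -> None:
        lengths = {len(s) for s in instances}
        if len(lengths) > 1:
            raise ContractError(f"sequences of mixed lengths {sorted(lengths)}")
        if reference is not None and lengths and {len(reference[0])} != lengths:
            raise ContractError(
                f"sequence length {lengths.pop()} does not match model length "
                f"{len(reference[0])}"
            )


class RBFKernel:
    """RBF kernel adapter: instances are numeric vectors (or raw sequences,
    one-hot flattened on the fly)."""

    name = "rbf"

    def __init__(self, params: RBFKernelParams = RBFKernelParams()):
        self.params = params

    @staticmethod
    def _as_matrix(instances) -> np.ndarray:
        if len(instances) and isinstance(instances[0], str):
            return flatten_batch(list(instances))
        return np.asarray(instances, dtype=np.float64)

    def gram(self, rows, cols=None) -> np.ndarray:
        rows = self._as_matrix(rows)
        cols = None if cols is None else self._as_matrix(cols)
        return rbf_gram(rows, cols, self.params)

    def validate_instances(self, instances, reference=None) -> None:
        X = self._as_matrix(instances)
        if reference is not None:
            R = self._as_matrix(reference)
            if X.size and X.shape[1] != R.shape[1]:
                raise ContractError(
                    f"feature dimension {X.shape[1]} does not match model {R.shape[1]}"
                )


@dataclass(frozen=True)
class CascadeConfig:
    n_subsets: int = 8
    max_global_passes: int = 5
    C: float = 1.0
    kernel: object = field(default_factory=WDKernel)
    seed: int = 0
    tol: float = 1e-3  # per-node dual solver tolerance

    def validate(self) -> None:
        if self.n_subsets < 1 or (self.n_subsets & (self.n_subsets - 1)) != 0:
            raise ConfigurationError("n_subsets must be a power of two >= 1")
        if self.max_global_passes < 1:
            raise ConfigurationError("max_global_passes must be >= 1")
        if not self.C > 0:
            raise ConfigurationError("C must be positive")


@dataclass
class CascadeModel:
    """Final support-vector expansion: f(x) = sum_s alpha_s K(x_s, x) + b."""

    support_indices: np.ndarray  # indices into the training set
    dual_coefficients: np.ndarray  # signed alpha per support vector
    bias: float
    kernel: object
    support_instances: list
    config: CascadeConfig
    history: list  # per (pass, level): list of candidate-set sizes
    n_passes: int
    converged: bool
    calibration: tuple | None = None  # (slope, intercept) of sigmoid on scores


def _stratified_subsets(labels: np.ndarray, n_subsets: int, rng) -> list[np.ndarray]:
    """Deal each class's shuffled indices round-robin into n_subsets groups."""
    groups: list[list[int]] = [[] for _ in range(n_subsets)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            groups[j % n_subsets].append(int(i))
    return [np.array(sorted(g), dtype=int) for g in groups]


def _fit_node(gram: np.ndarray, labels: np.ndarray, idx: np.ndarray, config: CascadeConfig):
    """Fit one SVC on the sub-gram of ``idx``; return (global SV indices, svc)."""
    sub = gram[np.ix_(idx, idx)]
    y = labels[idx]
    svc = SVC(kernel="precomputed", C=config.C, tol=config.tol)
    svc.fit(sub, y)
    return idx[svc.support_], svc


def train_cascade(train_instances, labels, config: CascadeConfig) -> CascadeModel:
    """Run the cascade and return the final support-vector model.

    ``train_instances`` are strings for the WD kernel or numeric vectors (or
    strings, encoded on the fly) for the RBF kernel. Deterministic given
    ``config.seed``.
    """
    config.validate()
    labels = np.asarray(labels)
    n = len(train_instances)
    if n != len(labels):
        raise ContractError("instances and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise TrainingError("training data must contain both classes")
    if config.n_subsets > n:
        raise ConfigurationError(f"n_subsets={config.n_subsets} exceeds n={n}")

    gram = config.kernel.gram(train_instances)
    rng = np.random.default_rng(config.seed)
    level0 = _stratified_subsets(labels, config.n_subsets, rng)

    history: list[dict] = []
    feedback = np.array([], dtype=int)
    prev_support: set[int] | None = None
    final_svc = None
    final_idx = None
    converged = False
    n_passes = 0
    for pass_no in range(config.max_global_passes):
        n_passes = pass_no + 1
        sets = [np.unique(np.concatenate([s, feedback])) for s in level0]
        level = 0
        while True:
            sv_sets = []
            svcs = []
            for idx in sets:
                sv_idx, svc = _fit_node(gram, labels, idx, config)
                sv_sets.append(sv_idx)
                svcs.append((idx, svc))
            history.append(
                {
                    "pass": pass_no,
                    "level": level,
                    "input_sizes": [len(s) for s in sets],
                    "support_sizes": [len(s) for s in sv_sets],
                }
            )
            if len(sv_sets) == 1:
                final_idx, final_svc = svcs[0]
                support = sv_sets[0]
                break
            sets = [
                np.unique(np.concatenate(sv_sets[i : i + 2]))
                for i in range(0, len(sv_sets), 2)
            ]
            level += 1
        support_set = set(int(i) for i in support)
        if prev_support is not None and support_set == prev_support:
            converged = True
            break
        prev_support = support_set
        feedback = support
        if config.n_subsets == 1:
            # single-subset cascade is a plain SVM fit; feedback cannot change it
            converged = True
            break

    support_global = final_idx[final_svc.support_]
    model = CascadeModel(
        support_indices=support_global,
        dual_coefficients=final_svc.dual_coef_[0].copy(),
        bias=float(final_svc.intercept_[0]),
        kernel=config.kernel,
        support_instances=[train_instances[int(i)] for i in support_global],
        config=config,
        history=history,
        n_passes=n_passes,
        converged=converged,
    )
    return model


def decision_function(model: CascadeModel, instances) -> np.ndarray:
    """Scores sum_s alpha_s K(x_s, x) + b; empty input gives an empty array."""
    if len(instances) == 0:
        return np.zeros(0, dtype=np.float64)
    model.kernel.validate_instances(instances, reference=model.support_instances)
    cross = model.kernel.gram(list(instances), model.support_instances)  # (n, n_sv)
    return cross @ model.dual_coefficients + model.bias


def predict(model: CascadeModel, instances) -> np.ndarray:
    """Hard labels by the sign of the decision score (>0 -> positive class)."""
    return (decision_function(model, instances) > 0).astype(int)


def fit_calibration(model: CascadeModel, val_instances, val_labels) -> CascadeModel:
    """Fit a monotone sigmoid score->probability map on validation data.

    Needed because the SVM decision score is not a probability but the
    binary-cross-entropy metric requires one.
    """
    scores = decision_function(model, val_instances).reshape(-1, 1)
    lr = LogisticRegression(C=1e6)
    lr.fit(scores, np.asarray(val_labels))
    model.calibration = (float(lr.coef_[0, 0]), float(lr.intercept_[0]))
    return model


def predict_proba(model: CascadeModel, instances) -> np.ndarray:
    """Calibrated probabilities, clipped away from 0 and 1.

    Falls back to a unit-slope sigmoid of the raw score when no calibration
    has been fitted.
    """
    scores = decision_function(model, instances)
    a, b = model.calibration if model.calibration is not None else (1.0, 0.0)
    p = 1.0 / (1.0 + np.exp(-(a * scores + b)))
    return np.clip(p, 1e-15, 1 - 1e-15)


def grid_search(
    train_instances,
    train_labels,
    val_instances,
    val_labels,
    grid: list[dict],
    base_config: CascadeConfig = CascadeConfig(),
):
    """Train one cascade per grid cell and select by validation AUC-ROC.

    Each cell is a dict that may set ``C`` and either ``d`` (WD kernel) or
    ``gamma`` (RBF kernel). Ties break toward smaller C, then smaller d/gamma.
    Returns ``(best_params, report)`` with one report row per cell.
    """
    if not grid:
        raise ConfigurationError("parameter grid must be non-empty")
    rows = []
    for cell in grid:
        kernel = base_config.kernel
        if "d" in cell:
            kernel = WDKernel(WDKernelParams(d=int(cell["d"])))
        elif "gamma" in cell:
            kernel = RBFKernel(RBFKernelParams(gamma=float(cell["gamma"])))
        config = CascadeConfig(
            n_subsets=base_config.n_subsets,
            max_global_passes=base_config.max_global_passes,
            C=float(cell.get("C", base_config.C)),
            kernel=kernel,
            seed=base_config.seed,
            tol=base_config.tol,
        )
        model = train_cascade(train_instances, train_labels, config)
        scores = decision_function(model, val_instances)
        auc = _metrics.auc_roc(np.asarray(val_labels), scores)
        rows.append({**cell, "C": config.C, "val_auc": auc})
    report = pd.DataFrame(rows)
    secondary = "d" if "d" in report.columns else ("gamma" if "gamma" in report.columns else None)
    order = report.sort_values(
        by=["val_auc", "C"] + ([secondary] if secondary else []),
        ascending=[False, True] + ([True] if secondary else []),
        kind="stable",
    )
    best = order.iloc[0].to_dict()
    best.pop("val_auc")
    return best, report
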