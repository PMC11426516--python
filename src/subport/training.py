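"""Feature assembly and gradient-boosted classifier training.

Each transporter-molecule pair is represented as the concatenation of a
protein embedding and a molecule representation (ECFP bits, a learned
embedding, or a one-hot index vector).  Binary pair classifiers and 7-way
substrate-class classifiers are gradient-boosted tree ensembles; their
hyperparameters are chosen by seeded random search over explicit ranges,
scored by mean Matthews correlation (or accuracy) across identity-
constrained cross-validation folds, optionally on a subset of validation
pairs (e.g. eukaryote-only model selection).  Binary decisions use the
fixed threshold score > 0.5.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import xgboost as xgb

from .evaluation import binary_metrics
from .records import InteractionPair, Label

__all__ = [
    "FeatureRecipe",
    "assemble_features",
    "HyperparameterSpace",
    "CVResult",
    "cross_validate",
    "TrainedClassifier",
    "train_final",
    "predict",
    "predict_labels",
]


@dataclass(frozen=True)
class FeatureRecipe:
    """Names the protein backend and molecule representation in use."""

    protein_backend: str
    molecule_representation: str  # "ecfp" | "learned" | "onehot"


def assemble_features(
    pairs: Sequence[InteractionPair],
    protein_vectors: Mapping[str, np.ndarray],
    molecule_vectors: Mapping[str, np.ndarray],
    recipe: FeatureRecipe,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate protein and molecule vectors row-wise, labels as 1/0.

    Row ``i`` is ``concat(protein_vectors[t_i], molecule_vectors[m_i])`` for
    pair ``i``; order follows the input.  Missing features are a fatal error
    listing the offending accessions.
    """
    missing_p = sorted({p.transporter_id for p in pairs} - set(protein_vectors))
    missing_m = sorted({p.chebi_id for p in pairs} - set(molecule_vectors))
    if missing_p or missing_m:
        raise KeyError(
            f"missing features under recipe {recipe}: "
            f"transporters {missing_p}, molecules {missing_m}"
        )
    if not pairs:
        return np.zeros((0, 0)), np.zeros((0,), dtype=int)
    rows = [
        np.concatenate(
            [
                np.asarray(protein_vectors[p.transporter_id], dtype=np.float32),
                np.asarray(molecule_vectors[p.chebi_id], dtype=np.float32),
            ]
        )
        for p in pairs
    ]
    labels = np.array([1 if p.label is Label.POSITIVE else 0 for p in pairs], dtype=int)
    return np.vstack(rows), labels


@dataclass(frozen=True)
class HyperparameterSpace:
    """Random-search ranges for the boosted-tree hyperparameters.

    Tuned knobs: learning rate, maximum tree depth, L2 (lambda) and L1
    (alpha) regularization, maximum delta step, minimum child weight,
    number of boosting rounds, and a weight in (0, 1] down-weighting the
    negative class (binary task).  ``prokaryote_weight`` optionally
    down-weights non-eukaryotic training pairs for a eukaryote-focused
    model; ``class_weighting`` enables inverse-frequency class weights for
    the multiclass task.
    """

    learning_rate: tuple[float, float] = (0.01, 0.31)  # log-uniform
    max_tree_depth: tuple[int, int] = (4, 13)
    l2_lambda: tuple[float, float] = (1e-3, 1e2)  # log-uniform
    l1_alpha: tuple[float, float] = (1e-3, 1e2)  # log-uniform
    max_delta_step: tuple[int, int] = (0, 5)
    min_child_weight: tuple[float, float] = (0.1, 15.0)
    n_rounds: tuple[int, int] = (50, 400)
    negative_class_weight: tuple[float, float] = (0.1, 1.0)
    prokaryote_weight: Optional[tuple[float, float]] = None
    class_weighting: bool = False

    def sample(self, rng: np.random.Generator) -> dict:
        def log_uniform(lo, hi):
            return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))

        point = {
            "learning_rate": log_uniform(*self.learning_rate),
            "max_tree_depth": int(rng.integers(self.max_tree_depth[0], self.max_tree_depth[1] + 1)),
            "l2_lambda": log_uniform(*self.l2_lambda),
            "l1_alpha": log_uniform(*self.l1_alpha),
            "max_delta_step": int(rng.integers(self.max_delta_step[0], self.max_delta_step[1] + 1)),
            "min_child_weight": float(rng.uniform(*self.min_child_weight)),
            "n_rounds": int(rng.integers(self.n_rounds[0], self.n_rounds[1] + 1)),
            "negative_class_weight": float(rng.uniform(*self.negative_class_weight)),
        }
        if self.prokaryote_weight is not None:
            point["prokaryote_weight"] = float(rng.uniform(*self.prokaryote_weight))
        return point


@dataclass
class CVResult:
    point: dict
    fold_metrics: list[float]
    mean_metric: float
    trial_index: int


def _booster_params(point: dict, n_classes: int, seed: int) -> dict:
    params = {
        "learning_rate": point["learning_rate"],
        "max_depth": point["max_tree_depth"],
        "reg_lambda": point["l2_lambda"],
        "reg_alpha": point["l1_alpha"],
        "max_delta_step": point["max_delta_step"],
        "min_child_weight": point["min_child_weight"],
        "tree_method": "hist",
        "seed": seed,
        "nthread": 1,
    }
    if n_classes <= 2:
        params["objective"] = "binary:logistic"
    else:
        params["objective"] = "multi:softprob"
        params["num_class"] = n_classes
    return params


def _sample_weights(
    labels: np.ndarray,
    point: dict,
    is_prokaryote: Optional[np.ndarray],
    class_weights: Optional[Mapping[int, float]],
) -> np.ndarray:
    w = np.ones(len(labels), dtype=float)
    if class_weights is not None:
        for cls, weight in class_weights.items():
            w[labels == cls] *= weight
    elif "negative_class_weight" in point and len(np.unique(labels)) <= 2:
        w[labels == 0] *= point["negative_class_weight"]
    if is_prokaryote is not None and "prokaryote_weight" in point:
        w[is_prokaryote] *= point["prokaryote_weight"]
    return w


def _fit_booster(
    X: np.ndarray,
    y: np.ndarray,
    point: dict,
    n_classes: int,
    seed: int,
    weights: np.ndarray,
) -> xgb.Booster:
    dtrain = xgb.DMatrix(X, label=y, weight=weights)
    return xgb.train(
        _booster_params(point, n_classes, seed), dtrain, num_boost_round=point["n_rounds"]
    )


def _metric_value(metric: str, labels: np.ndarray, scores: np.ndarray) -> float:
    if scores.ndim == 2:  # multiclass: argmax accuracy or one-vs-rest MCC mean
        predicted = scores.argmax(axis=1)
        if metric == "accuracy":
            return float(np.mean(predicted == labels))
        from .evaluation import multiclass_mcc

        return multiclass_mcc(labels, predicted)
    m = binary_metrics(labels, scores)
    return m.mcc if metric == "mcc" else m.accuracy


def cross_validate(
    space: HyperparameterSpace,
    fold_data: Sequence[tuple[np.ndarray, np.ndarray]],
    n_trials: int,
    metric: str = "mcc",
    selection_masks: Optional[Sequence[np.ndarray]] = None,
    prokaryote_masks: Optional[Sequence[np.ndarray]] = None,
    rng: np.random.Generator | int | None = None,
    n_classes: int = 2,
    class_weights: Optional[Mapping[int, float]] = None,
) -> CVResult:
    """Random hyperparameter search over rotating train/validation folds.

    ``fold_data`` holds one ``(X, y)`` block per fold; each trial trains on
    all-but-one fold and scores the held-out fold, rotating through all
    folds.  ``selection_masks`` (one boolean mask per fold) restricts metric
    computation to a validation subset — e.g. eukaryotic pairs only — while
    training still uses everything.  The best mean metric wins; ties break
    toward the earlier trial.  A single-class validation fold contributes
    MCC 0 with a warning.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if metric not in ("mcc", "accuracy"):
        raise ValueError(f"unsupported metric {metric!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_folds = len(fold_data)
    best: Optional[CVResult] = None
    for trial in range(n_trials):
        point = space.sample(rng)
        fold_metrics = []
        for held_out in range(n_folds):
            X_tr = np.vstack([fold_data[f][0] for f in range(n_folds) if f != held_out])
            y_tr = np.concatenate([fold_data[f][1] for f in range(n_folds) if f != held_out])
            prok_tr = None
            if prokaryote_masks is not None:
                prok_tr = np.concatenate(
                    [prokaryote_masks[f] for f in range(n_folds) if f != held_out]
                )
            weights = _sample_weights(y_tr, point, prok_tr, class_weights)
            booster = _fit_booster(X_tr, y_tr, point, n_classes, int(rng.integers(2**31)), weights)
            X_va, y_va = fold_data[held_out]
            scores = booster.predict(xgb.DMatrix(X_va))
            if selection_masks is not None:
                mask = selection_masks[held_out]
                y_va, scores = y_va[mask], scores[mask]
            fold_metrics.append(_metric_value(metric, y_va, scores))
        mean_metric = float(np.mean(fold_metrics))
        if best is None or mean_metric > best.mean_metric:
            best = CVResult(point, fold_metrics, mean_metric, trial)
    assert best is not None
    return best


@dataclass
class TrainedClassifier:
    """A fitted boosted-tree model plus the recipe that feeds it."""

    task: str  # "binary_pair" | "substrate_class"
    booster: xgb.Booster
    hyperparameters: dict
    recipe: FeatureRecipe
    n_features: int
    n_classes: int = 2
    decision_threshold: float = 0.5

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(directory / "model.json"))
        sidecar = {
            "task": self.task,
            "hyperparameters": self.hyperparameters,
            "recipe": asdict(self.recipe),
            "n_features": self.n_features,
            "n_classes": self.n_classes,
            "decision_threshold": self.decision_threshold,
        }
        (directory / "metadata.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "TrainedClassifier":
        directory = Path(directory)
        booster = xgb.Booster()
        booster.load_model(str(directory / "model.json"))
        meta = json.loads((directory / "metadata.json").read_text())
        return cls(
            task=meta["task"],
            booster=booster,
            hyperparameters=meta["hyperparameters"],
            recipe=FeatureRecipe(**meta["recipe"]),
            n_features=meta["n_features"],
            n_classes=meta["n_classes"],
            decision_threshold=meta["decision_threshold"],
        )


def train_final(
    point: dict,
    X: np.ndarray,
    y: np.ndarray,
    recipe: FeatureRecipe,
    task: str = "binary_pair",
    n_classes: int = 2,
    seed: int = 0,
    is_prokaryote: Optional[np.ndarray] = None,
    class_weights: Optional[Mapping[int, float]] = None,
) -> TrainedClassifier:
    """Fit the final model with the selected hyperparameters on all data."""
    if len(X) == 0:
        raise ValueError("training data must be nonempty")
    present = np.unique(y)
    if task == "binary_pair" and len(present) < 2:
        raise ValueError("binary training data must contain both classes")
    weights = _sample_weights(y, point, is_prokaryote, class_weights)
    booster = _fit_booster(X, y, point, n_classes, seed, weights)
    return TrainedClassifier(
        task=task,
        booster=booster,
        hyperparameters=point,
        recipe=recipe,
        n_features=X.shape[1],
        n_classes=n_classes,
    )


def predict(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Scores in [0,1] (binary) or row-stochastic score matrix (multiclass)."""
    if X.size == 0:
        if model.n_classes > 2:
            return np.zeros((0, model.n_classes))
        return np.zeros((0,))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model width {model.n_features}"
        )
    return model.booster.predict(xgb.DMatrix(X))


def predict_labels(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Hard labels: score > threshold (binary) or argmax (multiclass)."""
    scores = predict(model, X)
    if scores.ndim == 2:
        return scores.argmax(axis=1)
    return (scores > model.decision_threshold).astype(int)
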