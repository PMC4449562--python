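"""RBF-kernel SVM training, hyperparameter grid search, and persistence.

The classifier is a soft-margin SVM with kernel
``K(x, x') = exp(-gamma * ||x - x'||^2)`` (libsvm via scikit-learn, the
same solver family used in the original method).  Hyperparameters are
tuned by an exhaustive two-dimensional grid over geometric sequences
``C = 2^-12, 2^-10, ..., 2^2`` and ``gamma = 2^-5, 2^-3, ..., 2^9``
(64 candidates), scored by stratified inner-fold cross-validation on the
training rows only.  Ties are broken toward the smallest C, then the
smallest gamma.

For speed the grid search precomputes pairwise squared distances once per
inner fold and reuses them across all (C, gamma) candidates through
precomputed kernels; this is algebraically identical to refitting an RBF
SVM per candidate.
"""

from __future__ import annotations

import base64
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._errors import ModelFormatError, ValidationError
from .encoding import EncodingConfig, FeatureMatrix
from .selection import SelectionConfig, SelectionResult

#: C = 2^-12, 2^-10, ..., 2^2  (8 values)
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-12, 3, 2))
#: gamma = 2^-5, 2^-3, ..., 2^9  (8 values)
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 10, 2))

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SVMConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    tuning_metric: str = "auc"  # or "accuracy"

    def __post_init__(self) -> None:
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            raise ValidationError("c_grid must be non-empty with positive values")
        if not self.gamma_grid or any(g <= 0 for g in self.gamma_grid):
            raise ValidationError("gamma_grid must be non-empty with positive values")
        if self.inner_folds < 2:
            raise ValidationError("inner_folds must be >= 2")
        if self.tuning_metric not in ("auc", "accuracy"):
            raise ValidationError(f"unknown tuning_metric {self.tuning_metric!r}")

    @property
    def n_candidates(self) -> int:
        return len(self.c_grid) * len(self.gamma_grid)


def _check_two_classes(y: np.ndarray) -> tuple[int, int]:
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError(
            f"both classes required, got {n_pos} positive / {n_neg} negative rows"
        )
    return n_pos, n_neg


def _auc(y: np.ndarray, scores: np.ndarray) -> float:
    # Mann-Whitney rank form, ties counted 1/2 (shared with evaluation.roc_auc)
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def grid_search(
    matrix: FeatureMatrix,
    config: SVMConfig = SVMConfig(),
    seed: int = 0,
) -> tuple[float, float]:
    """Pick (C, gamma) by stratified inner-fold CV on the training matrix.

    Returns the candidate maximizing the tuning metric (mean over inner
    folds); ties go to the smallest C, then the smallest gamma.
    Deterministic given *seed*.
    """
    X, y = matrix.values, matrix.labels
    n_pos, n_neg = _check_two_classes(y)
    c_grid = tuple(sorted(config.c_grid))
    gamma_grid = tuple(sorted(config.gamma_grid))
    if len(c_grid) == 1 and len(gamma_grid) == 1:
        return c_grid[0], gamma_grid[0]
    if min(n_pos, n_neg) < config.inner_folds:
        raise ValidationError(
            f"inner {config.inner_folds}-fold CV needs >= {config.inner_folds} samples per "
            f"class (got {n_pos}/{n_neg}); use fewer folds"
        )
    skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed % (2**31))
    folds = []
    for tr, va in skf.split(X, y):
        d2_tr = euclidean_distances(X[tr], squared=True)
        d2_va = euclidean_distances(X[va], X[tr], squared=True)
        folds.append((tr, va, d2_tr, d2_va))

    scores = np.empty((len(c_grid), len(gamma_grid)))
    for gj, gamma in enumerate(gamma_grid):
        for ci, c in enumerate(c_grid):
            vals = []
            for tr, va, d2_tr, d2_va in folds:
                clf = SVC(kernel="precomputed", C=c)
                clf.fit(np.exp(-gamma * d2_tr), y[tr])
                dec = clf.decision_function(np.exp(-gamma * d2_va))
                if config.tuning_metric == "auc":
                    vals.append(_auc(y[va], dec))
                else:
                    pred = np.where(dec > 0, 1, -1)
                    vals.append(float((pred == y[va]).mean()))
            scores[ci, gj] = float(np.mean(vals))

    best_c, best_gamma, best = None, None, -np.inf
    for ci, c in enumerate(c_grid):
        for gj, gamma in enumerate(gamma_grid):
            if scores[ci, gj] > best:
                best, best_c, best_gamma = scores[ci, gj], c, gamma
    return best_c, best_gamma


@dataclass
class TrainedModel:
    """A fitted RBF SVM plus everything needed to score raw peptides."""

    svm: SVC
    chosen_c: float
    chosen_gamma: float
    selection: SelectionResult
    encoding: EncodingConfig
    window_size: int
    svm_config: SVMConfig = field(default_factory=SVMConfig)

    @property
    def n_selected_features(self) -> int:
        return self.selection.n_selected

    def decision_scores(self, matrix: FeatureMatrix) -> np.ndarray:
        return decision_scores(self, matrix)


def train(matrix: FeatureMatrix, c: float, gamma: float) -> SVC:
    """Fit a soft-margin RBF SVM at (c, gamma) on a selected-column matrix."""
    _check_two_classes(matrix.labels)
    clf = SVC(kernel="rbf", C=c, gamma=gamma)
    clf.fit(matrix.values, matrix.labels)
    return clf


def decision_scores(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Signed distances to the separating hyperplane; positive => epitope."""
    expected = model.selection.n_selected
    if matrix.n_features != expected:
        raise ValidationError(
            f"matrix has {matrix.n_features} columns but the model expects {expected} "
            "(apply the model's feature selection first)"
        )
    return np.asarray(model.svm.decision_function(matrix.values), dtype=np.float64)


# ---------------------------------------------------------------------------
# persistence: single JSON archive, metadata readable without unpickling
# ---------------------------------------------------------------------------


def _package_version() -> str:
    from . import __version__

    return __version__


def save_model(model: TrainedModel, path: Union[str, Path]) -> None:
    """Write a single-file archive: JSON metadata + serialized solver state."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": _package_version(),
        "chosen_c": model.chosen_c,
        "chosen_gamma": model.chosen_gamma,
        "window_size": model.window_size,
        "encoding": {"max_gap": model.encoding.max_gap, "alphabet": model.encoding.alphabet},
        "selection": {
            "p_cutoff": model.selection.config.p_cutoff,
            "selected_indices": model.selection.selected_indices.tolist(),
            "p_values": model.selection.p_values.tolist(),
        },
        "svm_config": {
            "c_grid": list(model.svm_config.c_grid),
            "gamma_grid": list(model.svm_config.gamma_grid),
            "inner_folds": model.svm_config.inner_folds,
            "tuning_metric": model.svm_config.tuning_metric,
        },
        "svm_state": base64.b64encode(pickle.dumps(model.svm)).decode("ascii"),
    }
    Path(path).write_text(json.dumps(payload))


def read_model_metadata(path: Union[str, Path]) -> dict:
    """Archive metadata (chosen C/gamma, encoding, selection sizes) without
    deserializing the solver."""
    payload = json.loads(Path(path).read_text())
    payload.pop("svm_state", None)
    return payload


def load_model(path: Union[str, Path]) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model archive format {version!r} is not supported (expected {MODEL_FORMAT_VERSION})"
        )
    for block in ("encoding", "selection", "svm_state"):
        if block not in payload:
            raise ModelFormatError(f"model archive is missing the {block!r} block")
    sel = payload["selection"]
    selection = SelectionResult(
        selected_indices=np.asarray(sel["selected_indices"], dtype=np.int64),
        p_values=np.asarray(sel["p_values"], dtype=np.float64),
        config=SelectionConfig(p_cutoff=sel["p_cutoff"]),
    )
    svm_cfg = payload.get("svm_config", {})
    return TrainedModel(
        svm=pickle.loads(base64.b64decode(payload["svm_state"])),
        chosen_c=payload["chosen_c"],
        chosen_gamma=payload["chosen_gamma"],
        selection=selection,
        encoding=EncodingConfig(**payload["encoding"]),
        window_size=payload["window_size"],
        svm_config=SVMConfig(
            c_grid=tuple(svm_cfg.get("c_grid", DEFAULT_C_GRID)),
            gamma_grid=tuple(svm_cfg.get("gamma_grid", DEFAULT_GAMMA_GRID)),
            inner_folds=svm_cfg.get("inner_folds", 5),
            tuning_metric=svm_cfg.get("tuning_metric", "auc"),
        ),
    )
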