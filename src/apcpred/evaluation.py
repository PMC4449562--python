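"""Stratified fivefold cross-validation with in-fold feature selection,
plus all performance metrics.

The evaluation protocol keeps feature selection and hyperparameter tuning
strictly inside each training partition: for every outer fold the t-test
filter is fit on the 4/5 training rows, the (C, gamma) grid search runs by
inner CV on those same rows, and only then is the held-out 1/5 scored.
Final reported metrics pool the concatenated held-out predictions of all
five folds ("the whole consideration of the five testing sets"); per-fold
metrics are also kept for transparency.

Threshold-dependent metrics (Acc, Sen, Spe, MCC) use a decision-value
threshold of 0; AUC is threshold-free and computed in the Mann-Whitney
rank form (probability a random positive outscores a random negative,
ties counting 1/2).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from ._errors import ValidationError
from .encoding import EncodingConfig, FeatureMatrix, encode_dataset
from .peptides import Peptide, PeptideDataset
from .selection import SelectionConfig, SelectionResult, apply_selection, select_features
from .svm import SVMConfig, TrainedModel, decision_scores, grid_search, train

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# confusion counts and threshold-dependent metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_predictions(cls, labels: np.ndarray, predictions: np.ndarray) -> "ConfusionCounts":
        labels = np.asarray(labels)
        predictions = np.asarray(predictions)
        return cls(
            tp=int(((labels == 1) & (predictions == 1)).sum()),
            fp=int(((labels == -1) & (predictions == 1)).sum()),
            tn=int(((labels == -1) & (predictions == -1)).sum()),
            fn=int(((labels == 1) & (predictions == -1)).sum()),
        )


@dataclass
class MetricSet:
    """Acc, Sen, Spe in [0, 1], MCC in [-1, 1], optional AUC."""

    acc: float
    sen: float
    spe: float
    mcc: float
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        d = {"acc": self.acc, "sen": self.sen, "spe": self.spe, "mcc": self.mcc}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Evaluate Acc = (TP+TN)/(TP+FP+TN+FN), Sen = TP/(TP+FN),
    Spe = TN/(TN+FP) and MCC = (TP*TN - FP*FN)/sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP)).

    Any zero factor under the MCC square root gives MCC = 0; an empty
    sensitivity/specificity denominator gives 0 for that metric.
    """
    if counts.total == 0:
        raise ValidationError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = (tp + tn) / counts.total
    sen = tp / (tp + fn) if (tp + fn) else 0.0
    spe = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricSet(acc=acc, sen=sen, spe=spe, mcc=mcc)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[float, list[tuple[float, float]]]:
    """AUC in the Mann-Whitney rank form plus the empirical ROC points.

    AUC is the probability a random positive outscores a random negative,
    with ties counted 1/2; it is invariant under strictly monotone score
    transforms.  The returned (fpr, tpr) points trace the full empirical
    ROC (no intermediate points dropped), so the trapezoid area over them
    equals the rank-form AUC.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes present")
    ranks = rankdata(s)
    auc = float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    fpr, tpr, _ = roc_curve(y, s, pos_label=1, drop_intermediate=False)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------


def stratified_kfold(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Fold index (0..k-1) per sample; class ratios preserved to within one
    sample per class per fold.  Deterministic given *seed*."""
    y = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("stratified folds require both classes present")
    if counts.min() < k:
        raise ValidationError(
            f"k={k} exceeds the smallest class size ({int(counts.min())})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    assignment = np.empty(len(y), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def _fold_seed(seed: int, fold: int) -> int:
    """Independent per-fold stream, kept below 2**31 for sklearn."""
    ss = np.random.SeedSequence([seed, fold])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# cross-validation report
# ---------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold: int
    counts: ConfusionCounts
    metrics: MetricSet
    chosen_c: float
    chosen_gamma: float
    n_selected_features: int
    selected_indices: np.ndarray


@dataclass
class CVReport:
    per_fold: list[FoldResult]
    pooled_counts: ConfusionCounts
    pooled: MetricSet
    roc_points: list[tuple[float, float]]
    seed: int
    config: dict
    samples: pd.DataFrame = field(repr=False)  # id, fold, label, score, prediction

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "pooled": {
                "counts": vars(self.pooled_counts),
                **self.pooled.as_dict(),
            },
            "per_fold": [
                {
                    "fold": f.fold,
                    "counts": vars(f.counts),
                    **f.metrics.as_dict(),
                    "chosen_c": f.chosen_c,
                    "chosen_gamma": f.chosen_gamma,
                    "n_selected_features": f.n_selected_features,
                }
                for f in self.per_fold
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.roc_points, columns=["fpr", "tpr"])


def _require_labeled_fixed_length(dataset: PeptideDataset) -> None:
    if dataset.window_size is None:
        raise ValidationError("cross-validation requires a fixed-length dataset")
    if len(dataset) == 0:
        raise ValidationError("dataset is empty")


def nested_cross_validate(
    dataset: PeptideDataset,
    encoding: EncodingConfig = EncodingConfig(),
    selection: SelectionConfig = SelectionConfig(),
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
    k: int = 5,
) -> CVReport:
    """Stratified k-fold (default fivefold) CV with in-fold selection/tuning.

    Encoding is computed once for all peptides (per-peptide and label-free,
    hence leakage-safe); the t-test filter, grid search and SVM fit see
    only each fold's training rows.
    """
    _require_labeled_fixed_length(dataset)
    matrix = encode_dataset(dataset, encoding)
    assignment = stratified_kfold(matrix.labels, k=k, seed=seed)

    fold_results: list[FoldResult] = []
    sample_rows: list[dict] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []

    for fold in range(k):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        train_m = matrix.rows(train_idx)
        test_m = matrix.rows(test_idx)
        try:
            sel = select_features(train_m, selection)
            train_sel = apply_selection(train_m, sel)
            test_sel = apply_selection(test_m, sel)
            fold_seed = _fold_seed(seed, fold)
            c, gamma = grid_search(train_sel, svm, seed=fold_seed)
            clf = train(train_sel, c, gamma)
        except Exception as exc:  # annotate with fold index, keep the type
            exc.args = (f"fold {fold}: {exc}",) + exc.args[1:]
            raise
        model = TrainedModel(
            svm=clf, chosen_c=c, chosen_gamma=gamma, selection=sel,
            encoding=encoding, window_size=dataset.window_size, svm_config=svm,
        )
        scores = decision_scores(model, test_sel)
        preds = np.where(scores > 0, 1, -1)
        counts = ConfusionCounts.from_predictions(test_m.labels, preds)
        metrics = compute_metrics(counts)
        metrics.auc, _ = roc_auc(test_m.labels, scores)
        logger.info(
            "fold %d: C=%g gamma=%g n_selected=%d auc=%.3f acc=%.3f",
            fold, c, gamma, sel.n_selected, metrics.auc, metrics.acc,
        )
        fold_results.append(
            FoldResult(
                fold=fold, counts=counts, metrics=metrics, chosen_c=c,
                chosen_gamma=gamma, n_selected_features=sel.n_selected,
                selected_indices=sel.selected_indices.copy(),
            )
        )
        pooled_counts = pooled_counts + counts
        all_scores.append(scores)
        all_labels.append(test_m.labels)
        for i, ridx in enumerate(test_idx):
            sample_rows.append(
                {
                    "id": matrix.peptide_ids[ridx],
                    "fold": fold,
                    "label": int(matrix.labels[ridx]),
                    "score": float(scores[i]),
                    "prediction": int(preds[i]),
                }
            )

    pooled_scores = np.concatenate(all_scores)
    pooled_labels = np.concatenate(all_labels)
    pooled = compute_metrics(pooled_counts)
    pooled.auc, roc_points = roc_auc(pooled_labels, pooled_scores)
    config = {
        "k": k,
        "max_gap": encoding.max_gap,
        "p_cutoff": selection.p_cutoff,
        "c_grid": list(svm.c_grid),
        "gamma_grid": list(svm.gamma_grid),
        "inner_folds": svm.inner_folds,
        "tuning_metric": svm.tuning_metric,
        "window_size": dataset.window_size,
    }
    return CVReport(
        per_fold=fold_results,
        pooled_counts=pooled_counts,
        pooled=pooled,
        roc_points=roc_points,
        seed=seed,
        config=config,
        samples=pd.DataFrame(sample_rows),
    )


def train_final_model(
    dataset: PeptideDataset,
    encoding: EncodingConfig = EncodingConfig(),
    selection: SelectionConfig = SelectionConfig(),
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
) -> TrainedModel:
    """Deployment path: selection and tuning on ALL rows, one fitted model."""
    _require_labeled_fixed_length(dataset)
    matrix = encode_dataset(dataset, encoding)
    sel = select_features(matrix, selection)
    matrix_sel = apply_selection(matrix, sel)
    c, gamma = grid_search(matrix_sel, svm, seed=seed)
    clf = train(matrix_sel, c, gamma)
    logger.info(
        "final model: C=%g gamma=%g n_selected=%d/%d", c, gamma, sel.n_selected, sel.n_total
    )
    return TrainedModel(
        svm=clf, chosen_c=c, chosen_gamma=gamma, selection=sel,
        encoding=encoding, window_size=dataset.window_size, svm_config=svm,
    )


def predict_peptides(model: TrainedModel, dataset: PeptideDataset) -> pd.DataFrame:
    """Encode, select and score peptides with a trained model.

    Returns a frame of (id, score, label) where label is the thresholded
    call at decision value 0.
    """
    for p in dataset:
        if len(p) != model.window_size:
            raise ValidationError(
                f"record {p.id!r} has length {len(p)}, model window is {model.window_size}"
            )
    matrix = encode_dataset(dataset, model.encoding, require_labels=False)
    matrix_sel = apply_selection(matrix, model.selection)
    scores = decision_scores(model, matrix_sel)
    return pd.DataFrame(
        {
            "id": dataset.ids(),
            "score": scores,
            "label": np.where(scores > 0, "positive", "negative"),
        }
    )


# ---------------------------------------------------------------------------
# parameter sweeps (max gap x p cutoff x window size)
# ---------------------------------------------------------------------------


def _crop_center(sequence: str, window: int) -> str:
    """Symmetric central crop; odd excess removed from the C-terminal side."""
    excess = len(sequence) - window
    if excess < 0:
        raise ValidationError(
            f"cannot crop a length-{len(sequence)} sequence to window {window}"
        )
    left = excess // 2
    return sequence[left : left + window]


def crop_dataset(dataset: PeptideDataset, window: int) -> PeptideDataset:
    """Centrally crop every peptide to *window* residues."""
    return PeptideDataset(
        [
            Peptide(id=p.id, sequence=_crop_center(p.sequence, window), label=p.label,
                    source=p.source)
            for p in dataset
        ]
    )


def parameter_sweep(
    dataset: PeptideDataset,
    I_values: Sequence[int],
    p_values: Sequence[float],
    window_sizes: Optional[Sequence[int]] = None,
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """One nested CV per (window, I, p) combination; one result row each.

    ``window_sizes=None`` keeps the dataset's own length.  Individual
    failures are logged and marked in the ``error`` column; the sweep
    continues.
    """
    _require_labeled_fixed_length(dataset)
    windows = list(window_sizes) if window_sizes else [dataset.window_size]
    rows = []
    for w in windows:
        ds_w = crop_dataset(dataset, w) if w != dataset.window_size else dataset
        for I in I_values:
            for p in p_values:
                row = {"window": w, "max_gap": I, "p_cutoff": p}
                try:
                    report = nested_cross_validate(
                        ds_w,
                        encoding=EncodingConfig(max_gap=I),
                        selection=SelectionConfig(p_cutoff=p),
                        svm=svm,
                        seed=seed,
                        k=k,
                    )
                    row.update(
                        auc=report.pooled.auc,
                        acc=report.pooled.acc,
                        sen=report.pooled.sen,
                        spe=report.pooled.spe,
                        mcc=report.pooled.mcc,
                        n_features_selected_mean=float(
                            np.mean([f.n_selected_features for f in report.per_fold])
                        ),
                        n_features_total=400 * (I + 1),
                        error="",
                    )
                except Exception as exc:
                    logger.warning("sweep combination w=%s I=%s p=%s failed: %s", w, I, p, exc)
                    row.update(
                        auc=np.nan, acc=np.nan, sen=np.nan, spe=np.nan, mcc=np.nan,
                        n_features_selected_mean=np.nan,
                        n_features_total=400 * (I + 1),
                        error=str(exc),
                    )
                rows.append(row)
    return pd.DataFrame(rows)
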