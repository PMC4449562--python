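"""Per-feature two-sample Student's t-test filtering.

Each APC feature column is compared between epitope and non-epitope rows
with the classic pooled-variance two-sample t-test; columns with two-sided
p below the cutoff are kept.  A cutoff of exactly 1.0 is the documented
no-filter sentinel (all columns retained).  The filter is always fit on
training rows only and the resulting column subset is then applied
unchanged to held-out rows — the mechanism that keeps cross-validation
leakage-free.

No multiple-testing correction is applied: the cutoff itself is a tuned
model parameter (the sweep tries 0.2, 0.4, 0.5, 0.6 and 1), not an
inference threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy import stats

from ._errors import ConfigError, ValidationError
from .encoding import FeatureMatrix


@dataclass(frozen=True)
class SelectionConfig:
    """t-test filter settings; ``p_cutoff=1.0`` disables filtering."""

    p_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cutoff <= 1.0):
            raise ConfigError(f"p_cutoff must be in (0, 1], got {self.p_cutoff}")


@dataclass
class SelectionResult:
    """Selected column indices plus the full per-feature p-value vector."""

    selected_indices: np.ndarray  # sorted ascending
    p_values: np.ndarray
    config: SelectionConfig

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)

    @property
    def n_total(self) -> int:
        return len(self.p_values)

    def to_tsv(self, path: Union[str, Path], feature_names: list[str]) -> None:
        sel = set(self.selected_indices.tolist())
        with open(path, "w") as fh:
            fh.write("feature\tp_value\tselected\n")
            for j, name in enumerate(feature_names):
                fh.write(f"{name}\t{self.p_values[j]!r}\t{int(j in sel)}\n")


def t_test_per_feature(matrix: FeatureMatrix) -> np.ndarray:
    """Two-sided pooled-variance t-test p-value for every feature column.

    Degrees of freedom are ``n_pos + n_neg - 2``.  Columns with zero pooled
    variance get p = 1 when the group means agree (pure noise by
    construction) and p = 0 when they differ.
    """
    pos = matrix.values[matrix.labels == 1]
    neg = matrix.values[matrix.labels == -1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            f"t-test needs >=2 samples per class, got {len(pos)} positive / {len(neg)} negative"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(pos, neg, axis=0, equal_var=True)
    # zero pooled variance -> scipy yields nan; resolve by the mean rule
    ss_pos = pos.var(axis=0, ddof=1)
    ss_neg = neg.var(axis=0, ddof=1)
    degenerate = (ss_pos + ss_neg) == 0.0
    if degenerate.any():
        equal_means = pos.mean(axis=0) == neg.mean(axis=0)
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    return np.asarray(p, dtype=np.float64)


def select_features(matrix: FeatureMatrix, config: SelectionConfig) -> SelectionResult:
    """Fit the filter on a TRAINING matrix: keep columns with p < cutoff.

    The inequality is strict; ``p_cutoff == 1.0`` keeps every column.  An
    empty selection is a configuration error (raise rather than silently
    training on nothing).
    """
    p = t_test_per_feature(matrix)
    if config.p_cutoff == 1.0:
        selected = np.arange(matrix.n_features)
    else:
        selected = np.flatnonzero(p < config.p_cutoff)
    if len(selected) == 0:
        raise ConfigError(
            f"no feature passed p < {config.p_cutoff}; increase the cutoff "
            "(p_cutoff=1.0 disables filtering)"
        )
    return SelectionResult(selected_indices=selected, p_values=p, config=config)


def apply_selection(matrix: FeatureMatrix, result: SelectionResult) -> FeatureMatrix:
    """Restrict *matrix* to the selected columns (training or held-out rows)."""
    from .encoding import FeatureSpace

    if matrix.n_features != result.n_total:
        raise ValidationError(
            f"selection was fit on {result.n_total} columns but matrix has {matrix.n_features}"
        )
    sub_space = FeatureSpace(
        config=matrix.space.config,
        pairs=[matrix.space.pairs[j] for j in result.selected_indices],
    )
    return FeatureMatrix(
        values=matrix.values[:, result.selected_indices],
        labels=matrix.labels,
        space=sub_space,
        peptide_ids=matrix.peptide_ids,
    )
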