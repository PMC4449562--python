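"""Amino acid anchoring pair composition (APC) encoding.

A peptide is decomposed into all ordered residue pairs separated by exactly
``i`` intervening residues, for every gap ``i`` from 0 up to a maximum gap
``I``.  Each pair ``X.{i}Y`` is a feature; its value in a peptide of length
``l`` is ``k / (l - i - 1)`` where ``k`` is the number of positions ``p``
with ``sequence[p] == X`` and ``sequence[p + i + 1] == Y``.  The denominator
is the number of length-(i+2) windows in the peptide, so for a peptide of
standard residues the 400 features at a given gap sum to exactly 1.  The
full feature space has ``400 * (I + 1)`` dimensions.

Degenerate residues (B, J, O, U, X, Z) are never counted as pair members,
but the denominator keeps the window geometry, so they dilute the
composition rather than renormalizing it.

Canonical feature order is gap-major, then first letter, then second
letter, both in alphabet order: ``A.{0}A, A.{0}C, ..., Y.{0}Y, A.{1}A, ...``
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .peptides import Label, Peptide, PeptideDataset

#: the 20 standard residues in alphabetical order — the default feature alphabet
STANDARD_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_PAIR_RE = re.compile(r"^([A-Z])\.\{(\d+)\}([A-Z])$")


@dataclass(frozen=True)
class EncodingConfig:
    """Encoder settings: maximum gap ``I`` and the feature alphabet."""

    max_gap: int = 3
    alphabet: str = STANDARD_ALPHABET

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValidationError(f"max_gap must be >= 0, got {self.max_gap}")
        if len(self.alphabet) != 20 or len(set(self.alphabet)) != 20:
            raise ValidationError("alphabet must contain exactly 20 unique letters")

    @property
    def n_features(self) -> int:
        return 400 * (self.max_gap + 1)


@dataclass(frozen=True, order=True)
class AnchoringPair:
    """An ordered residue pair with ``gap`` intervening positions, ``X.{i}Y``."""

    gap: int
    first: str
    second: str

    @property
    def name(self) -> str:
        return f"{self.first}.{{{self.gap}}}{self.second}"

    @classmethod
    def from_name(cls, name: str) -> "AnchoringPair":
        m = _PAIR_RE.match(name.strip())
        if not m:
            raise ValidationError(f"malformed anchoring pair name {name!r}; expected 'X.{{i}}Y'")
        return cls(first=m.group(1), gap=int(m.group(2)), second=m.group(3))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class FeatureSpace:
    """The ordered list of all anchoring pairs for a configuration."""

    config: EncodingConfig
    pairs: list[AnchoringPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def names(self) -> list[str]:
        return [p.name for p in self.pairs]

    def index_of(self, pair: AnchoringPair) -> int:
        alpha = self.config.alphabet
        if pair.gap > self.config.max_gap:
            raise ValidationError(f"pair {pair.name} exceeds max_gap={self.config.max_gap}")
        return pair.gap * 400 + alpha.index(pair.first) * 20 + alpha.index(pair.second)


def enumerate_features(config: EncodingConfig) -> FeatureSpace:
    """All ``400*(I+1)`` anchoring pairs in canonical (gap-major) order."""
    pairs = [
        AnchoringPair(gap=i, first=a, second=b)
        for i in range(config.max_gap + 1)
        for a in config.alphabet
        for b in config.alphabet
    ]
    return FeatureSpace(config=config, pairs=pairs)


def _residue_indices(sequence: str, alphabet: str) -> np.ndarray:
    lut = {ch: k for k, ch in enumerate(alphabet)}
    return np.fromiter((lut.get(ch, -1) for ch in sequence), dtype=np.int64, count=len(sequence))


def encode(peptide: Union[Peptide, str], config: EncodingConfig) -> np.ndarray:
    """APC feature vector of one peptide (length ``400*(max_gap+1)``).

    Gaps too wide for the sequence (``l - i - 1 <= 0``) contribute an
    all-zero block; no division is performed for them.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else normalize_for_encoding(peptide)
    l = len(seq)
    idx = _residue_indices(seq, config.alphabet)
    out = np.zeros(config.n_features, dtype=np.float64)
    for i in range(config.max_gap + 1):
        denom = l - i - 1
        if denom <= 0:
            continue
        a = idx[: l - i - 1]
        b = idx[i + 1 :]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            codes = a[ok] * 20 + b[ok]
            counts = np.bincount(codes, minlength=400)
            out[i * 400 : (i + 1) * 400] = counts / denom
    return out


def normalize_for_encoding(sequence: str) -> str:
    from .peptides import normalize_sequence

    return normalize_sequence(sequence)


@dataclass
class FeatureMatrix:
    """Peptides x features table of APC weights with an aligned +/-1 label vector."""

    values: np.ndarray  # (n_peptides, n_features) float64
    labels: np.ndarray  # (n_peptides,) int in {+1, -1}, or 0 for unlabeled rows
    space: FeatureSpace
    peptide_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.space):
            raise ValidationError(
                f"feature matrix has {self.values.shape[1] if self.values.ndim == 2 else '?'} "
                f"columns; feature space has {len(self.space)}"
            )
        if len(self.labels) != self.values.shape[0] or len(self.peptide_ids) != self.values.shape[0]:
            raise ValidationError("labels/ids not aligned with matrix rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix(
            values=self.values[idx],
            labels=self.labels[idx],
            space=self.space,
            peptide_ids=[self.peptide_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.space.names())
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.peptide_ids)
        return df

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_triplets(self, path: Union[str, Path]) -> None:
        """Sparse triplet export: one ``id<TAB>feature<TAB>value`` row per nonzero."""
        names = self.space.names()
        with open(path, "w") as fh:
            fh.write("id\tfeature\tvalue\n")
            rows, cols = np.nonzero(self.values)
            for r, c in zip(rows, cols):
                fh.write(f"{self.peptide_ids[r]}\t{names[c]}\t{self.values[r, c]!r}\n")


_LABEL_TO_SIGN = {Label.POSITIVE: 1, Label.NEGATIVE: -1}


def encode_dataset(
    dataset: PeptideDataset,
    config: EncodingConfig,
    require_labels: bool = True,
) -> FeatureMatrix:
    """Encode every peptide; labels map to +1 (positive) / -1 (negative).

    With ``require_labels=True`` (the training/evaluation path) an
    unknown-labeled peptide is an error; with ``False`` (the prediction
    path) unknown labels are stored as 0.
    """
    space = enumerate_features(config)
    values = np.zeros((len(dataset), config.n_features), dtype=np.float64)
    labels = np.zeros(len(dataset), dtype=np.int64)
    for r, p in enumerate(dataset):
        values[r] = encode(p, config)
        sign = _LABEL_TO_SIGN.get(p.label)
        if sign is None:
            if require_labels:
                raise ValidationError(
                    f"record {p.id!r} has label 'unknown'; a labeled matrix requires "
                    "positive/negative labels"
                )
            sign = 0
        labels[r] = sign
    return FeatureMatrix(values=values, labels=labels, space=space, peptide_ids=dataset.ids())
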