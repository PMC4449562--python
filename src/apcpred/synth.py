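"""Synthetic labeled peptide data with planted anchoring-pair enrichment.

The generator emulates the premise behind gapped-pair feature encoding:
certain ordered residue pairs occur more often in epitopes than in random
background peptides.  Negatives are i.i.d. background-sampled windows;
positives start as background windows and then, independently for each
planted pair with probability ``enrich_prob``, have the pair written at a
random valid position (the two anchor residues overwrite what was there,
preserving the fixed window length; later plants may overwrite earlier
ones).

The defaults — 200 positives + 200 negatives, 20-mer windows, 10 planted
pairs with gaps 0-3, enrichment probability 0.9, uniform residue
background — are the standard study conditions used throughout the test
suite and the acceptance script.

The generator tests the machinery, not biology: it makes no attempt to
mimic real epitope physicochemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .datasets import AntigenContext
from .encoding import STANDARD_ALPHABET, AnchoringPair
from .peptides import Label, Peptide, PeptideDataset

#: ten fixed planted pairs: 2 at gap 0, 2 at gap 1, 3 at gap 2, 3 at gap 3
DEFAULT_PLANTED_PAIRS: tuple[AnchoringPair, ...] = tuple(
    AnchoringPair.from_name(n)
    for n in (
        "W.{0}K", "F.{0}D",
        "Y.{1}H", "M.{1}E",
        "C.{2}R", "P.{2}N", "D.{2}W",
        "Q.{3}V", "H.{3}T", "K.{3}F",
    )
)


@dataclass
class PlantSpec:
    """Study conditions for one synthetic dataset."""

    pairs: tuple[AnchoringPair, ...] = DEFAULT_PLANTED_PAIRS
    enrich_prob: float = 0.9
    n_pos: int = 200
    n_neg: int = 200
    window: int = 20
    background_freqs: Optional[Sequence[float]] = None  # uniform over 20 when None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.enrich_prob <= 1.0):
            raise ValidationError("enrich_prob must be in [0, 1]")
        if self.n_pos < 0 or self.n_neg < 0 or self.window < 1:
            raise ValidationError("n_pos/n_neg must be >= 0 and window >= 1")
        for pair in self.pairs:
            if pair.gap > self.window - 2:
                raise ValidationError(
                    f"planted pair {pair.name} does not fit a window of {self.window}"
                )
        if self.background_freqs is not None:
            f = np.asarray(self.background_freqs, dtype=float)
            if f.shape != (20,) or (f < 0).any() or not np.isclose(f.sum(), 1.0):
                raise ValidationError("background_freqs must be 20 non-negative values summing to 1")

    @classmethod
    def from_json(cls, text: str) -> "PlantSpec":
        raw = json.loads(text)
        if "pairs" in raw:
            raw["pairs"] = tuple(AnchoringPair.from_name(n) for n in raw["pairs"])
        return cls(**raw)

    def to_json(self) -> str:
        d = {
            "pairs": [p.name for p in self.pairs],
            "enrich_prob": self.enrich_prob,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "window": self.window,
            "seed": self.seed,
        }
        if self.background_freqs is not None:
            d["background_freqs"] = list(self.background_freqs)
        return json.dumps(d, indent=2)


def _background_window(rng: np.random.Generator, spec: PlantSpec) -> str:
    probs = spec.background_freqs
    letters = rng.choice(np.array(list(STANDARD_ALPHABET)), size=spec.window, p=probs)
    return "".join(letters)


def _plant(seq: str, spec: PlantSpec, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pair in spec.pairs:
        if rng.random() < spec.enrich_prob:
            start = int(rng.integers(0, spec.window - pair.gap - 1))
            chars[start] = pair.first
            chars[start + pair.gap + 1] = pair.second
    return "".join(chars)


def generate(spec: PlantSpec) -> PeptideDataset:
    """Generate a labeled dataset per *spec*; byte-identical for equal
    spec + seed."""
    rng = np.random.default_rng(spec.seed)
    peptides: list[Peptide] = []
    for i in range(spec.n_pos):
        seq = _plant(_background_window(rng, spec), spec, rng)
        peptides.append(Peptide(id=f"pos{i + 1}", sequence=seq, label=Label.POSITIVE,
                                source="synthetic"))
    for i in range(spec.n_neg):
        peptides.append(
            Peptide(id=f"neg{i + 1}", sequence=_background_window(rng, spec),
                    label=Label.NEGATIVE, source="synthetic")
        )
    return PeptideDataset(peptides)


def permute_labels(dataset: PeptideDataset, seed: int) -> PeptideDataset:
    """Randomly reassign the existing labels across peptides (null control)."""
    rng = np.random.default_rng(seed)
    labels = [p.label for p in dataset]
    perm = rng.permutation(len(labels))
    return PeptideDataset(
        [
            Peptide(id=p.id, sequence=p.sequence, label=labels[perm[i]], source=p.source)
            for i, p in enumerate(dataset)
        ]
    )


def generate_antigens(
    n: int,
    length: int,
    embedded_epitopes: PlantSpec,
    seed: int = 0,
) -> tuple[PeptideDataset, pd.DataFrame]:
    """Random background proteins with one positive-style window embedded
    each at a recorded offset.

    Returns (antigens as an unknown-labeled dataset, offset table with
    columns antigen_id / epitope / start) suitable for window
    standardization and for scoring scan accuracy.  With
    ``embedded_epitopes.n_pos == 0`` no windows are embedded (plain random
    FASTA).
    """
    spec = embedded_epitopes
    if length < spec.window:
        raise ValidationError(
            f"antigen length {length} is shorter than the epitope window {spec.window}"
        )
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    embed = spec.n_pos > 0
    antigens: list[Peptide] = []
    rows: list[dict] = []
    for i in range(n):
        letters = rng.choice(np.array(list(STANDARD_ALPHABET)), size=length,
                             p=spec.background_freqs)
        seq = "".join(letters)
        if embed:
            window = _plant(_background_window(rng, spec), spec, rng)
            start = int(rng.integers(0, length - spec.window + 1))
            seq = seq[:start] + window + seq[start + spec.window :]
            rows.append({"antigen_id": f"ant{i + 1}", "epitope": window, "start": start})
        antigens.append(Peptide(id=f"ant{i + 1}", sequence=seq, label=Label.UNKNOWN,
                                source="synthetic"))
    table = pd.DataFrame(rows, columns=["antigen_id", "epitope", "start"])
    return PeptideDataset(antigens), table


def contexts_from_table(antigens: PeptideDataset, table: pd.DataFrame) -> list[AntigenContext]:
    """Join an offset table back onto its antigens for window standardization."""
    by_id = {p.id: p.sequence for p in antigens}
    return [
        AntigenContext(
            epitope=row.epitope, antigen=by_id[row.antigen_id], start=int(row.start),
            id=f"{row.antigen_id}:{int(row.start)}",
        )
        for row in table.itertuples()
    ]
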