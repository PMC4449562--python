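"""Build fixed-length labeled datasets from raw epitopes and background
proteins.

The recipe: epitopes shorter than the target window are extended
symmetrically with flanking residues from their source antigen (odd
deficit: extra residue C-terminal); longer epitopes are trimmed
symmetrically (odd excess: extra trim C-terminal).  Negatives are random
same-length windows drawn from a background protein set, rejecting any
window whose sequence equals a positive.  Near-duplicate peptides are then
removed with a greedy ungapped-identity filter at 80% identity — a
deliberately simplified stand-in for CD-HIT-style clustering, adequate for
fixed-length peptides but not byte-compatible with CD-HIT output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._errors import ResourceError, ValidationError, WindowRejection
from .peptides import Label, Peptide, PeptideDataset


@dataclass
class AntigenContext:
    """An epitope located within its source antigen."""

    epitope: str
    antigen: str
    start: int  # 0-based offset of the epitope in the antigen
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.antigen[self.start : self.start + len(self.epitope)] != self.epitope:
            raise ValidationError(
                f"epitope {self.id or self.epitope!r} not found at offset {self.start} "
                "of its antigen"
            )


def standardize_window(context: AntigenContext, window: int) -> Peptide:
    """Standardize one epitope to *window* residues using its antigen.

    Raises :class:`WindowRejection` when the antigen cannot supply enough
    flanking residues.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    e = len(context.epitope)
    seq_id = context.id or f"{context.epitope[:8]}@{context.start}"
    if e == window:
        out = context.epitope
    elif e > window:
        excess = e - window
        trim_n = excess // 2  # odd excess: extra trim C-terminal
        out = context.epitope[trim_n : trim_n + window]
    else:
        deficit = window - e
        ext_n = deficit // 2  # odd deficit: extra residue C-terminal
        ext_c = deficit - ext_n
        left_avail = context.start
        right_avail = len(context.antigen) - (context.start + e)
        take_left = min(ext_n, left_avail)
        take_right = min(ext_c, right_avail)
        short = deficit - take_left - take_right
        if short > 0:  # one flank exhausted: borrow from the other
            extra_left = min(short, left_avail - take_left)
            take_left += extra_left
            short -= extra_left
            extra_right = min(short, right_avail - take_right)
            take_right += extra_right
            short -= extra_right
        if short > 0:
            raise WindowRejection(
                f"{seq_id}: antigen too short to extend epitope to {window} residues "
                f"(missing {short})"
            )
        out = context.antigen[context.start - take_left : context.start + e + take_right]
    return Peptide(id=seq_id, sequence=out, label=Label.POSITIVE, source="standardize_window")


def standardize_all(
    contexts: list[AntigenContext], window: int
) -> tuple[PeptideDataset, list[tuple[str, str]]]:
    """Standardize many epitopes; returns (dataset, [(id, rejection reason)])."""
    kept: list[Peptide] = []
    rejected: list[tuple[str, str]] = []
    for n, ctx in enumerate(contexts, start=1):
        cid = ctx.id or f"epi{n}"
        try:
            pep = standardize_window(ctx, window)
            pep.id = cid
            kept.append(pep)
        except WindowRejection as exc:
            rejected.append((cid, exc.reason))
    return PeptideDataset(kept), rejected


def sample_negatives(
    background: PeptideDataset,
    n: int,
    window: int,
    positives: PeptideDataset,
    seed: int = 0,
) -> PeptideDataset:
    """Draw *n* distinct windows uniformly over all (sequence, offset)
    positions of the background, rejecting windows equal to any positive.

    Deterministic given *seed* (a seeded permutation of all candidate
    positions is walked until *n* valid windows are found).
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    positions: list[tuple[int, int]] = []
    for si, p in enumerate(background):
        for off in range(len(p) - window + 1):
            positions.append((si, off))
    if not positions:
        raise ResourceError(f"no background sequence is >= {window} residues long")
    forbidden = set(positives.sequences())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positions))
    out: list[Peptide] = []
    for k in order:
        if len(out) == n:
            break
        si, off = positions[k]
        seq = background[si].sequence[off : off + window]
        if seq in forbidden:
            continue
        out.append(
            Peptide(
                id=f"neg{len(out) + 1}",
                sequence=seq,
                label=Label.NEGATIVE,
                source=f"{background[si].id}:{off}",
            )
        )
    if len(out) < n:
        raise ResourceError(
            f"could only sample {len(out)} of {n} requested negatives "
            f"({len(positions)} candidate windows, {len(forbidden)} forbidden sequences)"
        )
    return PeptideDataset(out)


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reduce_redundancy(dataset: PeptideDataset, identity_threshold: float = 0.8) -> PeptideDataset:
    """Greedy redundancy filter on same-length peptides.

    Walk the dataset in input order and keep a peptide iff its ungapped
    identity (matching positions / length) to every already-kept peptide
    is strictly below the threshold.  Idempotent and deterministic.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValidationError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    if dataset.window_size is None and len(dataset) > 0:
        raise ValidationError(
            "redundancy filtering requires same-length peptides; run standardize_window first"
        )
    kept: list[Peptide] = []
    for p in dataset:
        if all(_identity(p.sequence, q.sequence) < identity_threshold for q in kept):
            kept.append(p)
    return PeptideDataset(kept)
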