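"""Labeled peptide datasets and their FASTA/TSV dialects.

A :class:`Peptide` is a short amino-acid sequence with a label
(epitope / non-epitope / unknown) and optional provenance.  Sequences are
uppercased on construction and validated against the 20-letter standard
alphabet plus the degenerate set ``{B, J, O, U, X, Z}``; degenerate residues
are retained (and flagged) rather than dropped, but the feature encoder
never counts pairs involving them.

Two on-disk dialects are supported:

* FASTA, with the label carried in a ``|label=positive`` header suffix;
* headerless two/three-column TSV ``label<TAB>sequence[<TAB>id]``.

Both round-trip exactly (ids, sequences, labels).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._errors import ParseError, ValidationError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
DEGENERATE_RESIDUES = frozenset("BJOUXZ")
_ALLOWED = STANDARD_RESIDUES | DEGENERATE_RESIDUES


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


#: accepted TSV label tokens (case-insensitive)
LABEL_TOKENS = {
    "1": Label.POSITIVE,
    "positive": Label.POSITIVE,
    "pos": Label.POSITIVE,
    "0": Label.NEGATIVE,
    "negative": Label.NEGATIVE,
    "neg": Label.NEGATIVE,
}


def parse_label_token(token: str) -> Label:
    try:
        return LABEL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unknown label token {token!r}; accepted: 1/0, positive/negative, pos/neg"
        ) from None


def normalize_sequence(seq: str, record: str = "sequence") -> str:
    """Uppercase, strip whitespace, and validate the residue alphabet.

    Idempotent: ``normalize(normalize(s)) == normalize(s)``.
    """
    cleaned = "".join(seq.split()).upper()
    if not cleaned:
        raise ValidationError(f"{record}: sequence is empty")
    bad = set(cleaned) - _ALLOWED
    if bad:
        raise ValidationError(
            f"{record}: illegal residue character(s) {sorted(bad)!r}"
        )
    return cleaned


@dataclass
class Peptide:
    """One labeled amino-acid sequence."""

    id: str
    sequence: str
    label: Label = Label.UNKNOWN
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("peptide id must be non-empty")
        self.label = Label(self.label)
        self.sequence = normalize_sequence(self.sequence, record=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_degenerate(self) -> bool:
        return any(ch in DEGENERATE_RESIDUES for ch in self.sequence)


@dataclass
class PeptideDataset:
    """An ordered collection of peptides with unique ids.

    ``window_size`` is set automatically when every sequence shares one
    length (the fixed-window setting used for model building).
    """

    peptides: list[Peptide] = field(default_factory=list)
    window_size: Optional[int] = field(default=None)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise ValidationError(f"duplicate peptide id {p.id!r}")
            seen.add(p.id)
        lengths = {len(p) for p in self.peptides}
        inferred = lengths.pop() if len(lengths) == 1 else None
        if self.window_size is None:
            self.window_size = inferred
        elif inferred != self.window_size:
            raise ValidationError(
                f"window_size={self.window_size} but sequence lengths are not all equal to it"
            )

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def labels(self) -> list[Label]:
        return [p.label for p in self.peptides]

    def subset(self, indices: Iterable[int]) -> "PeptideDataset":
        return PeptideDataset([self.peptides[i] for i in indices])

    def count(self, label: Label) -> int:
        return sum(1 for p in self.peptides if p.label is label)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_LABEL_TAG = "|label="


def read_fasta(
    path: Union[str, Path],
    default_label: Label = Label.UNKNOWN,
) -> PeptideDataset:
    """Read a FASTA file into a dataset.

    The id is the header token before the first whitespace; a
    ``|label=positive`` suffix on that token overrides *default_label*.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(
                f"{path}: line {lineno}: sequence data before the first FASTA header"
            )
        break
    peptides: list[Peptide] = []
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        token = title.split()[0] if title.split() else ""
        if not token:
            raise ParseError(f"{path}: FASTA record with empty header")
        label = default_label
        if _LABEL_TAG in token:
            token, _, tag = token.partition(_LABEL_TAG)
            label = parse_label_token(tag)
        peptides.append(Peptide(id=token, sequence=seq, label=label, source=str(path)))
    return PeptideDataset(peptides)


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


def read_labeled_tsv(path: Union[str, Path], header: bool = False) -> PeptideDataset:
    """Read a two/three-column TSV: label, sequence, optional id.

    Ids are auto-generated (``pep1``, ``pep2``, ...) when the third column
    is absent.  Set ``header=True`` to skip one leading line.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 1 if header else 0
    n = 0
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) not in (2, 3):
            raise ParseError(
                f"{path}: line {lineno}: expected 2 or 3 tab-separated columns, got {len(cols)}"
            )
        label = parse_label_token(cols[0])
        n += 1
        pid = cols[2].strip() if len(cols) == 3 and cols[2].strip() else f"pep{n}"
        peptides.append(Peptide(id=pid, sequence=cols[1], label=label, source=str(path)))
    return PeptideDataset(peptides)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_dataset(
    dataset: PeptideDataset,
    path: Union[str, Path],
    format: str = "fasta",
) -> None:
    """Write *dataset* to *path* as ``fasta`` or ``tsv`` (round-trip safe)."""
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as fh:
            for p in dataset:
                tag = "" if p.label is Label.UNKNOWN else f"{_LABEL_TAG}{p.label.value}"
                fh.write(f">{p.id}{tag}\n{p.sequence}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            for p in dataset:
                if p.label is Label.UNKNOWN:
                    raise ValidationError(
                        f"record {p.id!r}: TSV format requires a positive/negative label"
                    )
                fh.write(f"{p.label.value}\t{p.sequence}\t{p.id}\n")
    else:
        raise ValidationError(f"unknown dataset format {format!r} (use 'fasta' or 'tsv')")


def read_dataset(path: Union[str, Path], default_label: Label = Label.UNKNOWN) -> PeptideDataset:
    """Read FASTA or TSV, sniffing the format from the first character."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return read_fasta(path, default_label=default_label)
    return read_labeled_tsv(path)
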