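"""Reading, validating, labeling, splitting and folding DNA sequence datasets.

Datasets are two-class collections of DNA records: essential genes form the
positive class (label 1) and non-essential genes the negative class (label 0).
Labels are supplied either by reading one FASTA file per class or by pairing a
single FASTA with a tab-separated (id, label) table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
# IUPAC nucleotide ambiguity codes other than N; collapsed to N on input.
_AMBIGUITY_CODES = frozenset("RYSWKMBDHV")


@dataclass(frozen=True)
class LabeledSequence:
    """One DNA record: identifier, uppercase bases over {A,C,G,T,N}, binary label.

    ``label`` is 1 for essential genes and 0 for non-essential genes.
    """

    id: str
    bases: str
    label: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r} has empty bases")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}; "
                "bases must be normalized to A,C,G,T,N"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Dataset:
    """Ordered collection of labeled sequences with unique ids."""

    records: list[LabeledSequence] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sequence id {dup!r} in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.records)

    def __getitem__(self, i: int) -> LabeledSequence:
        return self.records[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        y = self.labels
        return int(np.sum(y == 0)), int(np.sum(y == 1))

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Dataset":
        return Dataset(
            records=[self.records[i] for i in indices],
            name=name or self.name,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions with a seed for reproducible splits."""

    train_fraction: float = 0.8
    validation_fraction: float = 0.1
    test_fraction: float = 0.1
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if not all(0.0 < f < 1.0 for f in fracs):
            raise ValueError(f"each fraction must lie in (0,1), got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fracs)!r}")


def _normalize_bases(raw: str, record_id: str) -> str:
    bases = raw.upper()
    present_ambiguity = set(bases) & _AMBIGUITY_CODES
    if present_ambiguity:
        logger.warning(
            "record %s: ambiguity codes %s collapsed to N",
            record_id,
            sorted(present_ambiguity),
        )
        bases = "".join("N" if b in _AMBIGUITY_CODES else b for b in bases)
    bad = set(bases) - _VALID_BASES
    if bad:
        raise ValueError(
            f"record {record_id!r} contains non-nucleotide characters {sorted(bad)}"
        )
    return bases


def read_fasta(path: str | Path, label: int) -> Dataset:
    """Read a FASTA file whose records all carry one binary class label.

    Bases are uppercased; IUPAC ambiguity codes other than N are collapsed to
    N with a logged warning. Record order is preserved. Raises on a missing or
    empty file, duplicate ids, or non-nucleotide characters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        LabeledSequence(id=rec.id, bases=_normalize_bases(str(rec.seq), rec.id), label=label)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Dataset(records=records, name=path.stem)


def read_labeled_fasta(fasta_path: str | Path, labels_path: str | Path) -> Dataset:
    """Read one FASTA plus a TSV label table with columns (id, label).

    Every FASTA record must appear in the table with a 0/1 label.
    """
    labels_path = Path(labels_path)
    if not labels_path.exists():
        raise FileNotFoundError(labels_path)
    label_map: dict[str, int] = {}
    for line_no, line in enumerate(labels_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{labels_path}:{line_no}: expected two tab-separated columns")
        seq_id, label_str = parts
        if seq_id in label_map:
            raise ValueError(f"{labels_path}: duplicate id {seq_id!r}")
        if label_str not in ("0", "1"):
            raise ValueError(f"{labels_path}:{line_no}: label must be 0 or 1, got {label_str!r}")
        label_map[seq_id] = int(label_str)

    unlabeled = read_fasta(fasta_path, label=0)
    records = []
    for rec in unlabeled:
        if rec.id not in label_map:
            raise ValueError(f"record {rec.id!r} has no entry in {labels_path}")
        records.append(LabeledSequence(id=rec.id, bases=rec.bases, label=label_map[rec.id]))
    return Dataset(records=records, name=Path(fasta_path).stem)


def write_fasta(ds: Dataset, fasta_path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write a dataset to FASTA, optionally with a TSV (id, label) table."""
    seq_records = [
        SeqRecord(Seq(r.bases), id=r.id, description=f"label={r.label}") for r in ds
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    if labels_path is not None:
        Path(labels_path).write_text("".join(f"{r.id}\t{r.label}\n" for r in ds))


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Apportion n items to parts, rounding quotas by largest remainder.

    Ties in the fractional parts are broken in part order (train first).
    """
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def split_dataset(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset, Dataset]:
    """Partition a dataset into train/validation/test sets.

    Stratified mode apportions each class independently with a
    largest-remainder rounding rule, so per-class proportions match the spec
    within one record. The partition is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train_fraction, spec.validation_fraction, spec.test_fraction)

    if spec.stratified:
        groups = [np.flatnonzero(ds.labels == c) for c in (0, 1)]
        if any(len(g) == 0 for g in groups):
            raise ValueError("stratified split requires both classes present")
    else:
        groups = [np.arange(len(ds))]

    parts: list[list[int]] = [[], [], []]
    for group in groups:
        shuffled = rng.permutation(group)
        counts = _largest_remainder_counts(len(group), fractions)
        start = 0
        for part, c in zip(parts, counts):
            part.extend(shuffled[start : start + c].tolist())
            start += c

    names = ("train", "validation", "test")
    return tuple(  # type: ignore[return-value]
        ds.subset(sorted(part), name=f"{ds.name}-{nm}") for part, nm in zip(parts, names)
    )


def make_folds(ds: Dataset, n_folds: int, seed: int = 0) -> list[tuple[Dataset, Dataset]]:
    """Stratified k-fold partition: list of (training, held-out) dataset pairs.

    Held-out folds are disjoint and cover the dataset; each class needs at
    least ``n_folds`` records.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    y = ds.labels
    for c in (0, 1):
        if int(np.sum(y == c)) < n_folds:
            raise ValueError(f"class {c} has fewer than {n_folds} records")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(ds)), y)):
        folds.append(
            (
                ds.subset(train_idx.tolist(), name=f"{ds.name}-fold{i}-train"),
                ds.subset(test_idx.tolist(), name=f"{ds.name}-fold{i}-heldout"),
            )
        )
    return folds


def write_id_list(ds: Dataset, path: str | Path) -> None:
    """Write the record ids of a split/fold, one per line, for audit."""
    Path(path).write_text("".join(f"{r.id}\n" for r in ds))
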