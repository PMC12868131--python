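"""Sequence/label input-output and data partitioning.

Reads labelled protein sequences (FASTA + id→label TSV), produces the
outer train/test split (default 8:2) and the stratified k-fold
cross-validation plan used throughout the pipeline.  With a 10-fold plan
on the 80% train/val portion, each CV round trains on 72% and validates
on 8% of the full dataset.

Split arithmetic is fixed as ``|train| = floor((1 - test_fraction) * N)``
so that a 13,488-record dataset at 8:2 yields exactly 10,790 train and
2,698 test records.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: nonstandard one-letter codes accepted on input; descriptor code maps them to X
NONSTANDARD = "BJOUXZ"
VALID_LETTERS = frozenset(AMINO_ACIDS + NONSTANDARD)


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending header."""


@dataclass(frozen=True)
class ProteinRecord:
    """One labelled amino-acid sequence — the unit of classification.

    ``label`` is 1 for MHC, 0 for non-MHC, and ``None`` for
    prediction-only input.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue letters {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test id partition."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    test_fraction: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": list(self.train_ids),
                    "test_ids": list(self.test_ids),
                    "test_fraction": self.test_fraction,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["train_ids"]), tuple(d["test_ids"]),
            d["test_fraction"], d["seed"],
        )


@dataclass(frozen=True)
class CVPlan:
    """Stratified fold assignment over the train/val ids."""

    n_folds: int
    fold_assignments: Mapping[str, int]
    val_fraction_within_fold: float
    seed: int = 0

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_assignments.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_assignments.items() if f != fold]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_folds": self.n_folds,
                    "fold_assignments": dict(self.fold_assignments),
                    "val_fraction_within_fold": self.val_fraction_within_fold,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CVPlan":
        d = json.loads(Path(path).read_text())
        return cls(
            d["n_folds"], d["fold_assignments"],
            d["val_fraction_within_fold"], d["seed"],
        )


def read_labels(path: str | Path) -> dict[str, int]:
    """Read an ``id <tab> label`` TSV (header row optional)."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label'")
        ident, value = parts
        if lineno == 1 and value.lower() in ("label", "class", "y"):
            continue  # header
        try:
            labels[ident] = int(value)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer label {value!r}") from exc
    return labels


def read_fasta(
    path: str | Path, labels: Mapping[str, int] | None = None
) -> list[ProteinRecord]:
    """Read FASTA into :class:`ProteinRecord` objects, order preserved.

    When a ``labels`` table is given every FASTA id must appear in it;
    missing ids raise with the full missing list.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaParseError(f"empty sequence under header {entry.id!r} in {path}")
        records.append(ProteinRecord(entry.id, seq))
    if not records:
        warnings.warn(f"{path}: no FASTA entries found", stacklevel=2)
    if labels is not None:
        missing = [r.id for r in records if r.id not in labels]
        if missing:
            raise KeyError(f"ids missing from label table: {missing}")
        records = [
            ProteinRecord(r.id, r.sequence, int(labels[r.id])) for r in records
        ]
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} has no label")
        lines.append(f"{r.id}\t{r.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def _by_class(records: Sequence[ProteinRecord]) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} unlabelled; cannot stratify")
        out.setdefault(r.label, []).append(r.id)
    return out


def stratified_split(
    records: Sequence[ProteinRecord],
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> SplitPlan:
    """Deterministic train/test split with per-class balance.

    ``|train| = floor((1 - test_fraction) * N)``; the test set receives
    per-class counts by largest remainder, so each class deviates from
    ``class_fraction * |test|`` by at most one record.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    n_train = int(np.floor((1.0 - test_fraction) * n))
    n_test = n - n_train
    rng = np.random.default_rng(seed)

    if not stratify:
        order = list(ids)
        rng.shuffle(order)
        return SplitPlan(tuple(order[:n_train]), tuple(order[n_train:]),
                         test_fraction, seed)

    groups = _by_class(records)
    for label, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"class {label} has fewer than 2 members; cannot stratify")
    # largest-remainder apportionment of the test set across classes
    labels_sorted = sorted(groups)
    exact = {lb: len(groups[lb]) / n * n_test for lb in labels_sorted}
    take = {lb: int(np.floor(exact[lb])) for lb in labels_sorted}
    leftover = n_test - sum(take.values())
    for lb in sorted(labels_sorted, key=lambda lb: exact[lb] - take[lb], reverse=True):
        if leftover <= 0:
            break
        take[lb] += 1
        leftover -= 1
    train: list[str] = []
    test: list[str] = []
    for lb in labels_sorted:
        members = sorted(groups[lb])
        rng.shuffle(members)
        test.extend(members[: take[lb]])
        train.extend(members[take[lb]:])
    return SplitPlan(tuple(train), tuple(test), test_fraction, seed)


def make_cv_folds(
    train_val: Sequence[ProteinRecord], n_folds: int = 10, seed: int = 0
) -> CVPlan:
    """Stratified k-fold plan; fold sizes differ by at most one.

    Ids are shuffled per class under ``seed`` then dealt round-robin
    across folds, so the per-fold class fraction stays within one count
    of the global fraction and the assignment is reproducible.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(train_val) < n_folds:
        raise ValueError(
            f"n_folds={n_folds} exceeds number of records ({len(train_val)})"
        )
    rng = np.random.default_rng(seed)
    groups = _by_class(train_val)
    assignment: dict[str, int] = {}
    offset = 0
    for lb in sorted(groups):
        members = sorted(groups[lb])
        rng.shuffle(members)
        for j, ident in enumerate(members):
            assignment[ident] = (offset + j) % n_folds
        offset += len(members)  # stagger classes so fold sizes stay even
    return CVPlan(
        n_folds=n_folds,
        fold_assignments=assignment,
        val_fraction_within_fold=1.0 / n_folds,
        seed=seed,
    )


def make_cv_folds_from_labels(
    labels: Mapping[str, int], n_folds: int = 10, seed: int = 0
) -> CVPlan:
    """Fold plan from an id→label mapping (for feature tables without records)."""
    records = [ProteinRecord(i, "A", int(lb)) for i, lb in labels.items()]
    return make_cv_folds(records, n_folds=n_folds, seed=seed)
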