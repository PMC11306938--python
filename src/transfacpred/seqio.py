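"""Sequence I/O and dataset curation.

Reads and writes protein FASTA, validates sequences against the 20-letter
standard amino-acid alphabet, applies the curation rules used to build
TF / non-TF training sets (GO-based labelling, removal of sequences with
non-natural residues, exact-duplicate removal), and produces the stratified
train / independent split.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: The 20 standard amino acids in fixed alphabetical order. Every vector
#: index in the feature encoders follows this ordering.
NATURAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_NATURAL_SET = frozenset(NATURAL_AA)

#: Class labels for the binary task. TF is the positive class throughout.
TF = "TF"
NON_TF = "nonTF"

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its FASTA identifier.

    ``seq`` is stored uppercase; ``L`` is the residue count.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def L(self) -> int:
        return len(self.seq)

    def is_natural(self) -> bool:
        """True if every residue is one of the 20 standard amino acids."""
        return set(self.seq) <= _NATURAL_SET


@dataclass
class LabeledDataset:
    """Parallel lists of records and TF / nonTF labels with unique ids."""

    records: list[SequenceRecord]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        bad = [l for l in self.labels if l not in (TF, NON_TF)]
        if bad:
            raise ValueError(f"labels must be '{TF}' or '{NON_TF}'; got {bad[:3]}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate id in dataset: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_pos(self) -> int:
        return sum(1 for l in self.labels if l == TF)

    @property
    def n_neg(self) -> int:
        return len(self.labels) - self.n_pos

    def label_map(self) -> dict[str, str]:
        return {r.id: l for r, l in zip(self.records, self.labels)}

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices], [self.labels[i] for i in indices]
        )


@dataclass
class GoRuleConfig:
    """GO term sets driving the TF labelling rule.

    An entry is a TF if it carries a TF-activity term, or if it carries both
    a DNA-binding term and a transcription-regulation term.
    """

    tf_activity_terms: set[str] = field(default_factory=set)
    dna_binding_terms: set[str] = field(default_factory=set)
    txn_regulation_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("tf_activity_terms", "dna_binding_terms", "txn_regulation_terms"):
            terms = getattr(self, name)
            if not terms:
                raise ValueError(f"{name} must be non-empty")
            bad = [t for t in terms if not _GO_ID_RE.match(t)]
            if bad:
                raise ValueError(f"invalid GO id(s) in {name}: {bad[:3]}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into SequenceRecords.

    Multi-line bodies are concatenated and residues uppercased. A non-blank
    line before the first header is a structural error and is reported with
    its line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if not s.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrapping (deterministic bytes)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (id, label in {TF, nonTF})."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or parts[1] not in (TF, NON_TF):
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>TF|nonTF'")
            out[parts[0]] = parts[1]
    return out


def write_label_map(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in labels.items():
            fh.write(f"{k}\t{v}\n")


def load_labeled_fasta(fasta: str | Path, labels: str | Path) -> LabeledDataset:
    """Pair a FASTA file with a label TSV into a LabeledDataset."""
    records = read_fasta(fasta)
    lmap = read_label_map(labels)
    missing = [r.id for r in records if r.id not in lmap]
    if missing:
        raise ValueError(f"no label for id(s): {missing[:3]}")
    return LabeledDataset(records, [lmap[r.id] for r in records])


def filter_nonnatural(
    records: Iterable[SequenceRecord],
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (kept, dropped) by the natural-residue criterion."""
    kept, dropped = [], []
    for rec in records:
        (kept if rec.is_natural() else dropped).append(rec)
    return kept, dropped


def deduplicate(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Drop records whose exact sequence string was already seen.

    First occurrence wins; input order is otherwise preserved. Redundancy is
    read as exact sequence identity — no similarity-threshold clustering.
    """
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.seq not in seen:
            seen.add(rec.seq)
            out.append(rec)
    return out


def go_label(entry_terms: set[str], cfg: GoRuleConfig) -> str:
    """Label one entry from its GO annotations.

    TF if it has a TF-activity term, or has both a DNA-binding term and a
    transcription-regulation term; nonTF otherwise. Terms are matched as
    flat sets — no ontology traversal.
    """
    if entry_terms & cfg.tf_activity_terms:
        return TF
    if entry_terms & cfg.dna_binding_terms and entry_terms & cfg.txn_regulation_terms:
        return TF
    return NON_TF


def stratified_split(
    ds: LabeledDataset, train_frac: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split into train / independent sets preserving the class ratio.

    Per class, round-half-up(train_frac * n_class) records go to train after
    a seeded shuffle. The two halves partition the input exactly; the split
    is reproducible for a fixed seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (TF, NON_TF):
        idx = [i for i, l in enumerate(ds.labels) if l == cls]
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has {len(idx)} member(s); cannot stratify")
        perm = rng.permutation(len(idx))
        n_train = int(math.floor(train_frac * len(idx) + 0.5))  # round half up
        shuffled = [idx[p] for p in perm]
        train_idx.extend(shuffled[:n_train])
        test_idx.extend(shuffled[n_train:])
    train_idx.sort()
    test_idx.sort()
    return ds.subset(train_idx), ds.subset(test_idx)
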