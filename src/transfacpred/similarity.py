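"""Alignment-based classification arm.

A labelled reference database is built from the training sequences; a query
is classified by the class of its top similarity hit (lowest e-value, ties
broken by higher bit score, then subject id), or NO_HIT when nothing passes
the e-value cutoff. The call converts to an additive vote for the hybrid
score: +w for TF, -w for nonTF, 0 for NO_HIT.

Two interchangeable engines satisfy the search contract:

* ``blast`` — external NCBI BLAST+ (``makeblastdb`` + ``blastp``, tabular
  output, default scoring parameters);
* ``pairwise`` — an in-process local aligner (BLOSUM62, gap open -11 /
  extend -1) with Karlin-Altschul e-values, so the package works with no
  external binary. Quadratic in sequence count; intended for small data.

Engine selection is ``auto`` by default: BLAST+ when its binaries are on
PATH, the in-process aligner otherwise.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import (
    TF,
    LabeledDataset,
    SequenceRecord,
    read_fasta,
    read_label_map,
    write_fasta,
    write_label_map,
)

NO_HIT = "NO_HIT"

#: Default e-value grid for cutoff sweeps, strictest first.
DEFAULT_CUTOFFS: tuple[float, ...] = (
    1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1e0, 1e1, 1e2, 2e2, 1e3,
)

# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1.
_KA_LAMBDA = 0.267
_KA_K = 0.041

_HIT_COLUMNS = ["qseqid", "sseqid", "pident", "evalue", "bitscore"]


class SearchEngineError(RuntimeError):
    """A similarity-search engine failed; carries the engine diagnostics."""


@dataclass(frozen=True)
class TopHitCall:
    """The alignment arm's verdict for one query."""

    query_id: str
    call: str  # TF, nonTF or NO_HIT
    subject_id: str | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if (self.call == NO_HIT) != (self.subject_id is None) or (
            self.call == NO_HIT
        ) != (self.evalue is None):
            raise ValueError("NO_HIT calls carry no subject/e-value; hits carry both")


@dataclass(frozen=True)
class ScanRow:
    """One row of an e-value sweep over labelled queries."""

    evalue_cutoff: float
    no_hit_positives: int
    prob_correct: float | None  # percent over queries that received a call


@dataclass
class ReferenceDB:
    """A formatted, labelled protein reference database on disk."""

    workdir: Path
    label_map: dict[str, str]
    n_sequences: int
    engine: str
    total_residues: int

    @property
    def fasta_path(self) -> Path:
        return self.workdir / "reference.fasta"

    @property
    def db_prefix(self) -> Path:
        return self.workdir / "reference"


def _resolve_engine(engine: str) -> str:
    if engine == "auto":
        return "blast" if shutil.which("blastp") else "pairwise"
    if engine not in ("blast", "pairwise"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "blast" and not (shutil.which("blastp") and shutil.which("makeblastdb")):
        raise SearchEngineError(
            "engine 'blast' requires the NCBI BLAST+ executables 'blastp' and "
            "'makeblastdb' on PATH; install BLAST+ or select engine='pairwise'"
        )
    return engine


def build_reference_db(
    train: LabeledDataset, workdir: str | Path, engine: str = "auto"
) -> ReferenceDB:
    """Format the training sequences into a labelled reference database.

    Writes the FASTA and id->label map under ``workdir`` (and the BLAST
    database volumes when the blast engine is selected). Rebuilding into an
    existing workdir replaces it wholesale, never leaving a half-built mix.
    """
    if len(train) == 0:
        raise ValueError("cannot build a reference database from an empty dataset")
    engine = _resolve_engine(engine)
    workdir = Path(workdir)
    workdir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".refdb-", dir=workdir.parent))
    try:
        write_fasta(train.records, staging / "reference.fasta")
        write_label_map(train.label_map(), staging / "labels.tsv")
        (staging / "engine.txt").write_text(engine + "\n")
        if engine == "blast":
            proc = subprocess.run(
                [
                    "makeblastdb",
                    "-in", str(staging / "reference.fasta"),
                    "-dbtype", "prot",
                    "-out", str(staging / "reference"),
                ],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise SearchEngineError(f"makeblastdb failed:\n{proc.stderr}")
        if workdir.exists():
            shutil.rmtree(workdir)
        staging.replace(workdir)
    finally:
        if staging.exists():
            shutil.rmtree(staging, ignore_errors=True)
    return ReferenceDB(
        workdir=workdir,
        label_map=train.label_map(),
        n_sequences=len(train),
        engine=engine,
        total_residues=sum(r.L for r in train.records),
    )


def load_reference_db(workdir: str | Path) -> ReferenceDB:
    """Re-open a database previously written by :func:`build_reference_db`."""
    workdir = Path(workdir)
    label_map = read_label_map(workdir / "labels.tsv")
    records = read_fasta(workdir / "reference.fasta")
    engine = (workdir / "engine.txt").read_text().strip()
    return ReferenceDB(
        workdir=workdir,
        label_map=label_map,
        n_sequences=len(records),
        engine=engine,
        total_residues=sum(r.L for r in records),
    )


def _blast_search(
    queries: Sequence[SequenceRecord], db: ReferenceDB, evalue_max: float
) -> pd.DataFrame:
    with tempfile.TemporaryDirectory(prefix="tfq-") as tmp:
        qpath = Path(tmp) / "queries.fasta"
        write_fasta(queries, qpath)
        proc = subprocess.run(
            [
                "blastp",
                "-query", str(qpath),
                "-db", str(db.db_prefix),
                "-evalue", repr(evalue_max),
                "-outfmt", "6 " + " ".join(_HIT_COLUMNS),
                "-num_threads", "1",
            ],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:
        raise SearchEngineError(f"blastp failed:\n{proc.stderr}")
    if not proc.stdout.strip():
        return pd.DataFrame(columns=_HIT_COLUMNS)
    return pd.read_csv(StringIO(proc.stdout), sep="\t", names=_HIT_COLUMNS)


def _pairwise_search(
    queries: Sequence[SequenceRecord], db: ReferenceDB, evalue_max: float
) -> pd.DataFrame:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    subjects = read_fasta(db.fasta_path)
    rows = []
    ln2 = math.log(2.0)
    for q in queries:
        for s in subjects:
            try:
                score = aligner.score(q.seq, s.seq)
            except ValueError as exc:  # residue outside the matrix alphabet
                raise SearchEngineError(f"pairwise alignment failed: {exc}") from exc
            bits = (_KA_LAMBDA * score - math.log(_KA_K)) / ln2
            evalue = q.L * db.total_residues * math.pow(2.0, -bits)
            if evalue <= evalue_max:
                rows.append((q.id, s.id, np.nan, evalue, bits))
    return pd.DataFrame(rows, columns=_HIT_COLUMNS)


def search_hits(
    queries: Sequence[SequenceRecord], db: ReferenceDB, evalue_max: float
) -> pd.DataFrame:
    """All hits up to ``evalue_max`` as a tabular DataFrame.

    Columns follow the BLAST tabular convention (qseqid, sseqid, pident,
    evalue, bitscore). The pident column is NaN for the pairwise engine.
    """
    if db.engine == "blast":
        return _blast_search(queries, db, evalue_max)
    return _pairwise_search(queries, db, evalue_max)


def _rank_and_call(
    hits: pd.DataFrame,
    queries: Sequence[SequenceRecord],
    db: ReferenceDB,
    evalue_cutoff: float,
    exclude_self: bool,
) -> list[TopHitCall]:
    hits = hits[hits["evalue"] <= evalue_cutoff]
    if exclude_self:
        hits = hits[hits["qseqid"] != hits["sseqid"]]
    # total order: best e-value, then highest bit score, then subject id
    best = (
        hits.sort_values(
            ["evalue", "bitscore", "sseqid"], ascending=[True, False, True], kind="mergesort"
        )
        .groupby("qseqid", sort=False)
        .first()
    )
    calls = []
    for q in queries:
        if q.id in best.index:
            row = best.loc[q.id]
            calls.append(
                TopHitCall(
                    query_id=q.id,
                    call=db.label_map[str(row["sseqid"])],
                    subject_id=str(row["sseqid"]),
                    evalue=float(row["evalue"]),
                )
            )
        else:
            calls.append(TopHitCall(query_id=q.id, call=NO_HIT))
    return calls


def batch_top_hit_calls(
    queries: Sequence[SequenceRecord],
    db: ReferenceDB,
    evalue_cutoff: float,
    exclude_self: bool = False,
) -> list[TopHitCall]:
    """Top-hit calls for many queries with a single engine invocation."""
    hits = search_hits(queries, db, evalue_cutoff)
    return _rank_and_call(hits, queries, db, evalue_cutoff, exclude_self)


def top_hit_call(
    query: SequenceRecord,
    db: ReferenceDB,
    evalue_cutoff: float = 1e-6,
    exclude_self: bool = False,
) -> TopHitCall:
    """Classify one query by its top hit in the reference database."""
    return batch_top_hit_calls([query], db, evalue_cutoff, exclude_self)[0]


def blast_vote(call: TopHitCall, weight: float = 0.5) -> float:
    """Convert a top-hit call into an additive vote: +w (TF), -w (nonTF), 0 (NO_HIT)."""
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if call.call == NO_HIT:
        return 0.0
    return weight if call.call == TF else -weight


def evalue_scan(
    queries: LabeledDataset,
    db: ReferenceDB,
    cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
    exclude_self: bool = False,
) -> list[ScanRow]:
    """Sweep e-value cutoffs and tabulate no-hit and correct-call rates.

    One search is run at the loosest cutoff and filtered per cutoff, so the
    no-hit count is non-increasing as the cutoff relaxes by construction.
    ``prob_correct`` is the percentage of correct calls among queries that
    received a call (no-hit queries are tabulated separately); it is None
    when no query received a call at that cutoff.
    """
    cutoffs = sorted(set(float(c) for c in cutoffs))
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    hits = search_hits(queries.records, db, max(cutoffs))
    truth = queries.label_map()
    rows = []
    for cutoff in cutoffs:
        calls = _rank_and_call(hits, queries.records, db, cutoff, exclude_self)
        no_hit_pos = sum(
            1 for c in calls if c.call == NO_HIT and truth[c.query_id] == TF
        )
        called = [c for c in calls if c.call != NO_HIT]
        correct = sum(1 for c in called if c.call == truth[c.query_id])
        prob = 100.0 * correct / len(called) if called else None
        rows.append(ScanRow(evalue_cutoff=cutoff, no_hit_positives=no_hit_pos, prob_correct=prob))
    return rows


def scan_table(rows: Sequence[ScanRow]) -> pd.DataFrame:
    """ScanRows as a DataFrame (E-value, no-hit positives, percent correct)."""
    return pd.DataFrame(
        {
            "evalue_cutoff": [r.evalue_cutoff for r in rows],
            "no_hit_positives": [r.no_hit_positives for r in rows],
            "prob_correct": [r.prob_correct for r in rows],
        }
    )
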