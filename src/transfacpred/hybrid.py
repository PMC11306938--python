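"""Score fusion and end-to-end batch prediction.

The hybrid decision adds the alignment-free arm's positive-class
probability (in [0, 1]) and the alignment arm's vote (+w / -w / 0), then
thresholds the sum. A confident agreeing similarity hit is decisive — the
sum crosses the threshold regardless of the classifier — while a NO_HIT
defers fully to the classifier. Vote weight and threshold both default to
0.5 and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .features import AAC_NAMES, DPC_NAMES, feature_matrix
from .models import TrainedModel, predict_score
from .seqio import _NATURAL_SET, TF, NON_TF, SequenceRecord, read_fasta
from .similarity import NO_HIT, ReferenceDB, batch_top_hit_calls, blast_vote

MODES = ("ml", "blast", "hybrid")


@dataclass(frozen=True)
class PredictionRow:
    """Per-sequence scores and the final TF / nonTF call."""

    id: str
    ml_score: float
    blast_vote: float
    hybrid_score: float
    label: str
    mode: str
    flagged_nonnatural: bool = False


def hybrid_score(ml: float, vote: float) -> float:
    """Sum of the alignment-free score and the alignment-based vote."""
    if not 0.0 <= ml <= 1.0:
        raise ValueError(f"ml score must be in [0, 1], got {ml}")
    return ml + vote


def classify(score: float, threshold: float = 0.5) -> str:
    """TF iff score >= threshold; the tie goes to TF."""
    return TF if score >= threshold else NON_TF


def _feature_kind(model: TrainedModel) -> str:
    names = tuple(model.feature_names)
    if names == AAC_NAMES:
        return "aac"
    if names == DPC_NAMES:
        return "dpc"
    if names == AAC_NAMES + DPC_NAMES:
        return "aac_dpc"
    raise ValueError(
        "model feature names match none of the known encoders (aac, dpc, aac_dpc)"
    )


def _clean_for_features(rec: SequenceRecord) -> tuple[SequenceRecord, bool]:
    """Strip non-natural residues so composition uses natural residues only."""
    if rec.is_natural():
        return rec, False
    cleaned = "".join(c for c in rec.seq if c in _NATURAL_SET)
    if not cleaned:
        raise ValueError(f"sequence {rec.id!r} has no natural residues to score")
    return SequenceRecord(id=rec.id, seq=cleaned), True


def predict_records(
    records: Sequence[SequenceRecord],
    model: TrainedModel | None = None,
    db: ReferenceDB | None = None,
    mode: str = "hybrid",
    evalue_cutoff: float = 1e-6,
    threshold: float = 0.5,
    vote_weight: float = 0.5,
    exclude_self: bool = False,
) -> list[PredictionRow]:
    """Predict TF / nonTF for each record, preserving input order.

    * ``ml`` mode labels from the classifier score alone (vote fixed at 0);
    * ``blast`` mode labels from the top-hit call, NO_HIT falling back to
      nonTF;
    * ``hybrid`` mode labels from classifier score + vote.

    Sequences with non-natural residues are not rejected: composition is
    computed over their natural residues only and the row is flagged.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode in ("ml", "hybrid") and model is None:
        raise ValueError(f"mode {mode!r} requires a trained model")
    if mode in ("blast", "hybrid") and db is None:
        raise ValueError(f"mode {mode!r} requires a reference database")

    flagged = {}
    scores = {}
    if model is not None and mode in ("ml", "hybrid"):
        cleaned = []
        for rec in records:
            c, f = _clean_for_features(rec)
            cleaned.append(c)
            flagged[rec.id] = f
        X = feature_matrix(cleaned, kind=_feature_kind(model))
        for rec, s in zip(records, predict_score(model, X)):
            scores[rec.id] = float(s)

    votes = {rec.id: 0.0 for rec in records}
    calls = {}
    if db is not None and mode in ("blast", "hybrid"):
        for call in batch_top_hit_calls(records, db, evalue_cutoff, exclude_self):
            calls[call.query_id] = call
            votes[call.query_id] = blast_vote(call, weight=vote_weight)

    rows = []
    for rec in records:
        ml = scores.get(rec.id, 0.0)
        vote = votes[rec.id] if mode != "ml" else 0.0
        if mode == "ml":
            score = ml
            label = classify(score, threshold)
        elif mode == "blast":
            call = calls[rec.id]
            score = vote
            label = NON_TF if call.call == NO_HIT else call.call
        else:
            score = hybrid_score(ml, vote)
            label = classify(score, threshold)
        rows.append(
            PredictionRow(
                id=rec.id,
                ml_score=ml,
                blast_vote=vote,
                hybrid_score=score if mode == "hybrid" else ml + vote,
                label=label,
                mode=mode,
                flagged_nonnatural=flagged.get(rec.id, False),
            )
        )
    return rows


def predict_pipeline(
    fasta: str | Path,
    model: TrainedModel | None = None,
    db: ReferenceDB | None = None,
    mode: str = "hybrid",
    evalue_cutoff: float = 1e-6,
    threshold: float = 0.5,
    vote_weight: float = 0.5,
) -> list[PredictionRow]:
    """Run batch prediction over a FASTA file (one row per input sequence)."""
    return predict_records(
        read_fasta(fasta),
        model=model,
        db=db,
        mode=mode,
        evalue_cutoff=evalue_cutoff,
        threshold=threshold,
        vote_weight=vote_weight,
    )


def rows_to_frame(rows: Sequence[PredictionRow]) -> pd.DataFrame:
    """Prediction rows as a DataFrame (id, ml_score, blast_vote, hybrid_score, label, mode)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in rows],
            "ml_score": [r.ml_score for r in rows],
            "blast_vote": [r.blast_vote for r in rows],
            "hybrid_score": [r.hybrid_score for r in rows],
            "label": [r.label for r in rows],
            "mode": [r.mode for r in rows],
        }
    )
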