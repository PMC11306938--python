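"""Composition-based and one-hot sequence encodings.

Three encoders are provided:

* amino-acid composition (AAC) — for residue type *i*, ``AAC_i = R_i / L``
  where ``R_i`` counts residue *i* and ``L`` is the sequence length; a
  vector of length 20;
* dipeptide composition (DPC) — for ordered pair *i* at gap *j*,
  ``DPC_i = D_ij / (L - j)`` where ``D_ij`` counts positions ``p`` with the
  pair ``(seq[p], seq[p+j])`` of type *i*; a vector of length 400 (20x20),
  with the standard adjacent-pair composition at ``j = 1``;
* one-hot — each residue becomes a 21-slot indicator row (20 natural
  residues by alphabetical index plus one permanently unused dummy slot;
  any non-natural symbol maps to the all-zero row).

The canonical internal scale is the fraction; percent is a presentation
option. Vector indices follow the fixed alphabetical residue ordering
ACDEFGHIKLMNPQRSTVWY.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd

from .seqio import NATURAL_AA, TF, NON_TF, LabeledDataset, SequenceRecord

#: Column labels for the 20 AAC features.
AAC_NAMES: tuple[str, ...] = tuple(NATURAL_AA)
#: Column labels for the 400 DPC features, in (first, second) lexicographic order.
DPC_NAMES: tuple[str, ...] = tuple(a + b for a, b in product(NATURAL_AA, repeat=2))

_AA_INDEX = {aa: i for i, aa in enumerate(NATURAL_AA)}


def _indices(rec: SequenceRecord) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in rec.seq), dtype=np.intp, count=rec.L)
    except KeyError as exc:
        raise ValueError(
            f"sequence {rec.id!r} contains non-natural residue {exc.args[0]!r}; "
            "apply filter_nonnatural first"
        ) from None


def aac(rec: SequenceRecord, scale: str = "fraction") -> np.ndarray:
    """Amino-acid composition vector of length 20.

    Entry *i* is the count of residue *i* divided by the sequence length,
    times 100 for ``scale='percent'``.
    """
    if scale not in ("fraction", "percent"):
        raise ValueError("scale must be 'fraction' or 'percent'")
    counts = np.bincount(_indices(rec), minlength=20).astype(float)
    vec = counts / rec.L
    return vec * 100.0 if scale == "percent" else vec


def dpc(rec: SequenceRecord, order_j: int = 1) -> np.ndarray:
    """Dipeptide composition vector of length 400 at gap ``order_j``.

    Counts ordered residue pairs separated by ``order_j`` positions and
    divides by ``L - order_j``. Requires ``L > order_j``.
    """
    if order_j < 1:
        raise ValueError("order_j must be >= 1")
    if rec.L <= order_j:
        raise ValueError(
            f"sequence {rec.id!r} has length {rec.L} <= order j={order_j}; "
            "dipeptide denominator would be non-positive"
        )
    idx = _indices(rec)
    pair_codes = idx[:-order_j] * 20 + idx[order_j:]
    counts = np.bincount(pair_codes, minlength=400).astype(float)
    return counts / (rec.L - order_j)


def combine_aac_dpc(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Concatenate an AAC vector and a DPC vector into a 420-feature vector."""
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.shape != (20,):
        raise ValueError(f"AAC block must have shape (20,), got {a.shape}")
    if d.shape != (400,):
        raise ValueError(f"DPC block must have shape (400,), got {d.shape}")
    return np.concatenate([a, d])


def one_hot(rec: SequenceRecord, max_len: int = 1000) -> np.ndarray:
    """One-hot matrix of shape (max_len, 21).

    Natural residues map to unit rows in the first 20 slots by alphabetical
    index; any other symbol gives an all-zero row; the 21st slot is never
    set. Sequences longer than ``max_len`` are right-truncated, shorter ones
    zero-padded.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    mat = np.zeros((max_len, 21), dtype=np.int8)
    for p, c in enumerate(rec.seq[:max_len]):
        i = _AA_INDEX.get(c)
        if i is not None:
            mat[p, i] = 1
    return mat


def feature_matrix(
    records: Iterable[SequenceRecord],
    kind: str = "aac",
    scale: str = "fraction",
    order_j: int = 1,
) -> pd.DataFrame:
    """Encode records into a feature DataFrame indexed by sequence id.

    ``kind`` is one of ``aac`` (20 columns), ``dpc`` (400) or ``aac_dpc``
    (420, AAC block first). Column names are the residue / dipeptide labels,
    so fitted models can verify feature identity at prediction time.
    """
    records = list(records)
    if kind == "aac":
        names: tuple[str, ...] = AAC_NAMES
        rows = [aac(r, scale=scale) for r in records]
    elif kind == "dpc":
        names = DPC_NAMES
        rows = [dpc(r, order_j=order_j) for r in records]
    elif kind == "aac_dpc":
        names = AAC_NAMES + DPC_NAMES
        rows = [combine_aac_dpc(aac(r, scale=scale), dpc(r, order_j=order_j)) for r in records]
    else:
        raise ValueError(f"unknown feature kind {kind!r}")
    data = np.vstack(rows) if rows else np.empty((0, len(names)))
    return pd.DataFrame(data, index=[r.id for r in records], columns=list(names))


def class_composition(ds: LabeledDataset) -> pd.DataFrame:
    """Per-class mean percent amino-acid composition.

    Returns a DataFrame with one row per class (TF, nonTF) and 20 columns:
    the unweighted mean over sequences of each sequence's percent AAC. Used
    to compare residue abundance between the classes.
    """
    out = {}
    for cls in (TF, NON_TF):
        recs = [r for r, l in zip(ds.records, ds.labels) if l == cls]
        if not recs:
            raise ValueError(f"class {cls!r} is empty")
        out[cls] = np.mean([aac(r, scale="percent") for r in recs], axis=0)
    return pd.DataFrame(out, index=list(AAC_NAMES)).T
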