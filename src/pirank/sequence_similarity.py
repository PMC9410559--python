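"""Normalized Smith-Waterman similarity between short RNA sequences.

The sequence kernel of the predictor: the similarity of two piRNAs is their
optimal local-alignment score normalized by the geometric mean of their
self-alignment scores,

    S_P(a, b) = SW(a, b) / sqrt(SW(a, a) * SW(b, b))  in [0, 1].

The alignment model is the classical linear-gap local DP

    H(i, j) = max(0, H(i-1, j-1) + s(a_i, b_j), H(i-1, j) + g, H(i, j-1) + g)

with a match/mismatch substitution score s and per-symbol gap penalty g < 0.
piRNAs are 24-31 nt, so exact DP over all pairs is cheap; all-against-all
matrices go through a numba kernel, single pairs through a plain-Python
reference implementation of the same recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "AlignmentScoring",
    "SimilarityMatrix",
    "smith_waterman",
    "normalized_similarity",
    "similarity_matrix",
    "cross_similarity",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Match/mismatch/linear-gap parameters of the local alignment DP.

    Defaults (+2 / -1 / -1) are a simple scheme with strictly positive
    self-scores; all three are configurable.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -1.0

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be > 0")
        if self.gap >= 0:
            raise ValueError("gap penalty must be < 0")


@dataclass
class SimilarityMatrix:
    """Similarity values in [0, 1] indexed by row/column identifiers."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("similarity matrix shape does not match id lists")
        if self.values.size and (self.values.min() < -1e-12
                                 or self.values.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        self.row_index = {r: i for i, r in enumerate(self.row_ids)}
        self.col_index = {c: j for j, c in enumerate(self.col_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, row_id: str) -> np.ndarray:
        return self.values[self.row_index[row_id]]

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.row_ids,
                     columns=self.col_ids).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "SimilarityMatrix":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index.astype(str)),
                   list(frame.columns.astype(str)), frame.to_numpy())


# ---------------------------------------------------------------------------
# Scalar reference DP
# ---------------------------------------------------------------------------


def smith_waterman(a: str, b: str, scoring: AlignmentScoring | None = None) -> float:
    """Raw Smith-Waterman local alignment score (plain-Python reference DP)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sc = scoring or AlignmentScoring()
    prev = [0.0] * (len(b) + 1)
    best = 0.0
    for i in range(1, len(a) + 1):
        cur = [0.0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            sub = sc.match if ai == b[j - 1] else sc.mismatch
            h = max(0.0, prev[j - 1] + sub, prev[j] + sc.gap, cur[j - 1] + sc.gap)
            cur[j] = h
            if h > best:
                best = h
        prev = cur
    return best


def normalized_similarity(a: str, b: str,
                          scoring: AlignmentScoring | None = None) -> float:
    """Self-score-normalized similarity in [0, 1]; 0 when SW(a, b) = 0."""
    sc = scoring or AlignmentScoring()
    raw = smith_waterman(a, b, sc)
    if raw == 0.0:
        return 0.0
    denom = np.sqrt(smith_waterman(a, a, sc) * smith_waterman(b, b, sc))
    return float(raw / denom)


# ---------------------------------------------------------------------------
# Batched numba kernels
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _encode(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    out = np.full((len(sequences), int(lengths.max())), -1, dtype=np.int8)
    for i, seq in enumerate(sequences):
        for j, ch in enumerate(seq):
            out[i, j] = _CODE[ch]
    return out, lengths


@njit(cache=True)
def _sw_pair(a, la, b, lb, match, mismatch, gap):  # pragma: no cover - numba
    prev = np.zeros(lb + 1, dtype=np.float64)
    cur = np.zeros(lb + 1, dtype=np.float64)
    best = 0.0
    for i in range(1, la + 1):
        cur[0] = 0.0
        ai = a[i - 1]
        for j in range(1, lb + 1):
            sub = match if ai == b[j - 1] else mismatch
            h = prev[j - 1] + sub
            if prev[j] + gap > h:
                h = prev[j] + gap
            if cur[j - 1] + gap > h:
                h = cur[j - 1] + gap
            if h < 0.0:
                h = 0.0
            cur[j] = h
            if h > best:
                best = h
        prev, cur = cur, prev
    return best


@njit(cache=True)
def _sw_cross(qc, ql, rc, rl, match, mismatch, gap):  # pragma: no cover
    out = np.empty((qc.shape[0], rc.shape[0]), dtype=np.float64)
    for i in range(qc.shape[0]):
        for j in range(rc.shape[0]):
            out[i, j] = _sw_pair(qc[i], ql[i], rc[j], rl[j],
                                 match, mismatch, gap)
    return out


@njit(cache=True)
def _sw_upper(codes, lens, match, mismatch, gap):  # pragma: no cover
    n = codes.shape[0]
    out = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i, n):
            out[i, j] = _sw_pair(codes[i], lens[i], codes[j], lens[j],
                                 match, mismatch, gap)
    return out


@njit(cache=True)
def _sw_self(codes, lens, match, mismatch, gap):  # pragma: no cover
    n = codes.shape[0]
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = _sw_pair(codes[i], lens[i], codes[i], lens[i],
                          match, mismatch, gap)
    return out


def similarity_matrix(seqs, scoring: AlignmentScoring | None = None) -> SimilarityMatrix:
    """All-against-all normalized similarities: square, symmetric, unit diagonal.

    Only the upper triangle is computed; the lower is mirrored, so symmetry is
    exact.
    """
    sc = scoring or AlignmentScoring()
    if len(seqs) == 0:
        raise ValueError("need at least one sequence")
    codes, lens = _encode(seqs.sequences)
    raw = _sw_upper(codes, lens, sc.match, sc.mismatch, sc.gap)
    self_scores = np.diag(raw).copy()
    denom = np.sqrt(np.outer(self_scores, self_scores))
    values = np.where(denom > 0, raw / denom, 0.0)
    values = np.clip(values, 0.0, 1.0)
    iu = np.triu_indices(len(seqs), k=1)
    values[(iu[1], iu[0])] = values[iu]
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(seqs.ids), list(seqs.ids), values)


def cross_similarity(query, reference,
                     scoring: AlignmentScoring | None = None) -> SimilarityMatrix:
    """Rectangular similarities of query sequences against a reference set."""
    sc = scoring or AlignmentScoring()
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("both sequence sets must be non-empty")
    qc, ql = _encode(query.sequences)
    rc, rl = _encode(reference.sequences)
    raw = _sw_cross(qc, ql, rc, rl, sc.match, sc.mismatch, sc.gap)
    q_self = _sw_self(qc, ql, sc.match, sc.mismatch, sc.gap)
    r_self = _sw_self(rc, rl, sc.match, sc.mismatch, sc.gap)
    denom = np.sqrt(np.outer(q_self, r_self))
    values = np.where(denom > 0, raw / denom, 0.0)
    values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(list(query.ids), list(reference.ids), values)
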