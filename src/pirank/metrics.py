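"""Grouped ranking metrics: NDCG@k, MAP, truncated ROCk, AUC and AUPR.

Every metric is computed per query piRNA over that query's candidate
diseases, then macro-averaged across queries.  Queries without a positive
candidate cannot be scored and are skipped (counted, not zero-filled); AUC
additionally requires at least one negative.

Conventions: binary relevance with gain 2^rel - 1 and discount
1/log2(position + 1) for NDCG; non-interpolated average precision for
MAP/AUPR; Mann-Whitney AUC with half credit for ties; ROCk is the truncated
ROC score used in ranked homolog retrieval -- the mean number of positives
retrieved before each of the first k false positives, normalized by k * T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ndcg_at_k",
    "average_precision",
    "roc_k",
    "auc",
    "aupr",
    "evaluate",
    "EvaluationReport",
]


def ndcg_at_k(labels, k: int) -> float:
    """NDCG at truncation k of an already-ranked binary label sequence.

    Returns 0.0 when the list has no positive (IDCG = 0).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels, dtype=np.float64)
    gains = 2.0 ** labels - 1.0
    disc = 1.0 / np.log2(np.arange(2, len(labels) + 2))
    dcg = float((gains[:k] * disc[: min(k, len(labels))]).sum())
    ideal = np.sort(gains)[::-1]
    idcg = float((ideal[:k] * disc[: min(k, len(labels))]).sum())
    return dcg / idcg if idcg > 0 else 0.0


def average_precision(labels) -> float:
    """Non-interpolated AP of a ranked binary label sequence."""
    labels = np.asarray(labels)
    positives = np.nonzero(labels > 0)[0]
    if len(positives) == 0:
        raise ValueError("average precision undefined without positives")
    hits = np.arange(1, len(positives) + 1)
    return float(np.mean(hits / (positives + 1)))


def roc_k(labels, k: int) -> float:
    """Truncated ROC score of a ranked binary label sequence.

    ROC_k = (1 / (k' * T)) * sum_{i=1..k'} t_i where t_i is the number of
    positives ranked above the i-th false positive, T the total positives and
    k' = min(k, #negatives).  A list with no negative is vacuously perfect
    (1.0).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(labels)
    total_pos = int((labels > 0).sum())
    if total_pos == 0:
        raise ValueError("ROCk undefined without positives")
    neg_positions = np.nonzero(labels == 0)[0]
    k_eff = min(k, len(neg_positions))
    if k_eff == 0:
        return 1.0
    pos_cum = np.cumsum(labels > 0)
    t = pos_cum[neg_positions[:k_eff]]
    return float(t.sum() / (k_eff * total_pos))


def auc(scores, labels) -> float:
    """Mann-Whitney AUC (ties get half credit); needs both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def _rank_labels(scores, labels) -> np.ndarray:
    order = np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
    return np.asarray(labels)[order]


def aupr(scores, labels) -> float:
    """Area under the precision-recall step curve (non-interpolated AP over
    the score-induced ranking, stable ties)."""
    ranked = _rank_labels(scores, labels)
    return average_precision(ranked)


@dataclass
class EvaluationReport:
    """Per-query metric table plus macro-averages over evaluable queries."""

    per_query: pd.DataFrame
    macro: dict[str, float]
    n_queries_evaluated: int
    n_queries_skipped: int

    def write_tsv(self, path) -> None:
        frame = self.per_query.copy()
        summary = pd.DataFrame([{"query": "MACRO_AVERAGE", **self.macro}])
        pd.concat([frame, summary], ignore_index=True).to_csv(
            path, sep="\t", index=False)

    def summary_text(self) -> str:
        lines = [f"{key}\t{value:.6f}" for key, value in self.macro.items()]
        lines.append(f"n_queries_evaluated\t{self.n_queries_evaluated}")
        lines.append(f"n_queries_skipped\t{self.n_queries_skipped}")
        return "\n".join(lines)


def evaluate(queries, k_list=(5, 10), roc_k_list=(1, 3, 5, 10)) -> EvaluationReport:
    """Evaluate per-query rankings and macro-average the metrics.

    ``queries`` is an iterable of ``(query_id, scores, labels)``; each query
    is scored over its own candidates only.  Queries without positives are
    skipped entirely; queries without negatives contribute to every metric
    except AUC (reported as NaN for that query and excluded from its macro
    mean).
    """
    rows = []
    n_skipped = 0
    for query_id, scores, labels in queries:
        labels = np.asarray(labels)
        if (labels > 0).sum() == 0:
            n_skipped += 1
            continue
        ranked = _rank_labels(scores, labels)
        row: dict = {
            "query": query_id,
            "n_candidates": len(labels),
            "n_positives": int((labels > 0).sum()),
        }
        both_classes = len(np.unique(labels)) == 2
        row["auc"] = auc(scores, labels) if both_classes else np.nan
        row["aupr"] = aupr(scores, labels)
        row["map"] = average_precision(ranked)
        for k in k_list:
            row[f"ndcg@{k}"] = ndcg_at_k(ranked, k)
        for k in roc_k_list:
            row[f"roc@{k}"] = roc_k(ranked, k)
        rows.append(row)
    if not rows:
        raise ValueError("no evaluable query (every query lacks positives)")
    per_query = pd.DataFrame(rows)
    metric_cols = [c for c in per_query.columns
                   if c not in ("query", "n_candidates", "n_positives")]
    macro = {c: float(per_query[c].mean(skipna=True)) for c in metric_cols}
    return EvaluationReport(per_query, macro, len(rows), n_skipped)
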