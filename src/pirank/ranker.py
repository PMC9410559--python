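"""LambdaMART: listwise gradient-boosted ranking of diseases per query piRNA.

Candidates for one query piRNA form a group; the model is an additive
ensemble of small regression trees fitted round by round to lambda gradients.
For a pair (i positive, j negative) within a group scored (s_i, s_j),

    rho        = 1 / (1 + exp(sigma * (s_i - s_j)))
    lambda_ij  = sigma * rho * |dNDCG@k(i, j)|
    w_ij       = sigma^2 * rho * (1 - rho) * |dNDCG@k(i, j)|

where |dNDCG@k(i, j)| is the change in NDCG@k from swapping i and j in the
current score-sorted order (stable ties by candidate input index).  Gains are
2^rel - 1 with binary relevance and the discount is 1/log2(position + 1),
zero beyond the truncation level k.  Each tree splits greedily by variance
reduction on the 4 stacked component scores and takes Newton leaf values
sum(lambda) / (sum(w) + eps).

Models serialize to a versioned, human-readable nested text format.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

_EPS = 1e-9
MODEL_FORMAT = "pirank-lambdamart"
MODEL_VERSION = 1

__all__ = [
    "RankerConfig",
    "SCENARIO_A_CONFIG",
    "SCENARIO_P_CONFIG",
    "RankedList",
    "compute_lambdas",
    "fit_tree",
    "LambdaMARTRanker",
    "train",
    "predict",
    "feature_usage",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class RankerConfig:
    """LambdaMART hyperparameters: ensemble size, NDCG truncation level k,
    shrinkage (learning rate) and leaves per tree."""

    n_trees: int = 100
    truncation_k: int = 10
    shrinkage: float = 0.1
    n_leaves: int = 10
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0 or self.truncation_k < 1 or self.n_leaves < 2:
            raise ValueError("invalid tree/truncation/leaf configuration")
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


#: Tuned configuration for the missing-association (known piRNA) scenario.
SCENARIO_A_CONFIG = RankerConfig(n_trees=120, truncation_k=14,
                                 shrinkage=0.22, n_leaves=3)
#: Tuned configuration for the cold-start (new piRNA) scenario.
SCENARIO_P_CONFIG = RankerConfig(n_trees=30, truncation_k=15,
                                 shrinkage=0.10, n_leaves=29)


@dataclass
class RankedList:
    """One query's candidates ordered best-first: (disease, score, rank)."""

    query: str
    entries: list[tuple[str, float, int]]


# ---------------------------------------------------------------------------
# Lambda gradients
# ---------------------------------------------------------------------------


def _discounts(ranks: np.ndarray, k: int) -> np.ndarray:
    disc = 1.0 / np.log2(ranks + 1.0)
    disc[ranks > k] = 0.0
    return disc


def _idcg(n_pos: int, k: int) -> float:
    top = min(n_pos, k)
    return float(np.sum(1.0 / np.log2(np.arange(1, top + 1) + 1.0)))


def compute_lambdas(scores: np.ndarray, labels: np.ndarray, k: int,
                    sigma: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-candidate lambda gradients and Newton weights for one group.

    Returns zeros when the group lacks a positive or a negative label.
    Within a group the lambdas sum to zero by antisymmetry.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(scores)
    lam = np.zeros(n)
    hess = np.zeros(n)
    pos = np.nonzero(labels > 0)[0]
    neg = np.nonzero(labels == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        return lam, hess
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    disc = _discounts(ranks, k)
    idcg = _idcg(len(pos), k)
    # Binary gains: |gain_i - gain_j| = 1, so the swap effect on NDCG@k is
    # just the discount difference over IDCG.
    delta = np.abs(disc[pos][:, None] - disc[neg][None, :]) / idcg
    rho = 1.0 / (1.0 + np.exp(sigma * (scores[pos][:, None] - scores[neg][None, :])))
    pair_lam = sigma * rho * delta
    pair_hess = sigma * sigma * rho * (1.0 - rho) * delta
    np.add.at(lam, pos, pair_lam.sum(axis=1))
    np.add.at(lam, neg, -pair_lam.sum(axis=0))
    np.add.at(hess, pos, pair_hess.sum(axis=1))
    np.add.at(hess, neg, pair_hess.sum(axis=0))
    return lam, hess


# ---------------------------------------------------------------------------
# Regression trees
# ---------------------------------------------------------------------------


def _leaf(targets: np.ndarray, weights: np.ndarray) -> dict:
    return {"value": float(targets.sum() / (weights.sum() + _EPS))}


def _best_split(X: np.ndarray, targets: np.ndarray, idx: np.ndarray):
    """Best (gain, feature, threshold, left_idx, right_idx) by SSE reduction."""
    n = len(idx)
    if n < 2:
        return None
    t = targets[idx]
    total = t.sum()
    base = total * total / n
    best = None
    best_gain = 1e-12
    for f in range(X.shape[1]):
        xs = X[idx, f]
        order = np.argsort(xs, kind="stable")
        xs_sorted = xs[order]
        t_sorted = t[order]
        csum = np.cumsum(t_sorted)[:-1]
        counts = np.arange(1, n)
        valid = xs_sorted[1:] != xs_sorted[:-1]
        if not valid.any():
            continue
        left = csum * csum / counts
        right = (total - csum) ** 2 / (n - counts)
        gains = np.where(valid, left + right - base, -np.inf)
        pos = int(np.argmax(gains))
        if gains[pos] > best_gain:
            best_gain = float(gains[pos])
            threshold = 0.5 * (xs_sorted[pos] + xs_sorted[pos + 1])
            mask = xs <= threshold
            best = (best_gain, f, float(threshold), idx[mask], idx[~mask])
    return best


def fit_tree(X: np.ndarray, targets: np.ndarray, weights: np.ndarray,
             n_leaves: int) -> dict:
    """Grow a best-first regression tree with at most ``n_leaves`` leaves.

    Splits maximize variance reduction of ``targets``; leaf values are Newton
    steps sum(targets) / (sum(weights) + eps).  Returns a nested dict with
    ``{"feature", "threshold", "left", "right"}`` internal nodes and
    ``{"value"}`` leaves.
    """
    X = np.asarray(X, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if len(X) == 0:
        raise ValueError("cannot fit a tree on zero samples")
    root_idx = np.arange(len(X))
    root: dict = _leaf(targets[root_idx], weights[root_idx])
    # Candidate heap of (gain, node-dict, split info); expand best gain first.
    candidates = []
    split = _best_split(X, targets, root_idx)
    if split is not None:
        candidates.append((root, split))
    n_current = 1
    while candidates and n_current < n_leaves:
        i_best = max(range(len(candidates)), key=lambda i: candidates[i][1][0])
        node, (gain, f, thr, left_idx, right_idx) = candidates.pop(i_best)
        left = _leaf(targets[left_idx], weights[left_idx])
        right = _leaf(targets[right_idx], weights[right_idx])
        node.pop("value")
        node.update(feature=int(f), threshold=thr, left=left, right=right)
        n_current += 1
        for child, child_idx in ((left, left_idx), (right, right_idx)):
            child_split = _best_split(X, targets, child_idx)
            if child_split is not None:
                candidates.append((child, child_split))
    return root


def _tree_predict(node: dict, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X))
    stack = [(node, np.arange(len(X)))]
    while stack:
        nd, idx = stack.pop()
        if "value" in nd:
            out[idx] = nd["value"]
        else:
            mask = X[idx, nd["feature"]] <= nd["threshold"]
            stack.append((nd["left"], idx[mask]))
            stack.append((nd["right"], idx[~mask]))
    return out


def _tree_splits(node: dict, counts: np.ndarray) -> None:
    if "value" not in node:
        counts[node["feature"]] += 1
        _tree_splits(node["left"], counts)
        _tree_splits(node["right"], counts)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class LambdaMARTRanker(BaseEstimator):
    """Gradient-boosted listwise ranker over grouped candidates.

    Follows the scikit-learn estimator protocol: ``fit(X, y, group=...)``
    where ``group`` assigns each row to its query, then ``predict(X)``
    returns ranking scores (higher = more likely associated).  Training is
    fully deterministic; ``seed`` is reserved for future stochastic options.

    Attributes
    ----------
    base_score_ : float
        Constant initial score (0.0).
    trees_ : list of dict
        Fitted regression trees in boosting order.
    n_features_in_ : int
        Number of stacked component features (4 in the standard pipeline).
    """

    def __init__(self, n_trees: int = 100, truncation_k: int = 10,
                 shrinkage: float = 0.1, n_leaves: int = 10,
                 sigma: float = 1.0, seed: int = 0):
        self.n_trees = n_trees
        self.truncation_k = truncation_k
        self.shrinkage = shrinkage
        self.n_leaves = n_leaves
        self.sigma = sigma
        self.seed = seed

    @classmethod
    def from_config(cls, config: RankerConfig) -> "LambdaMARTRanker":
        return cls(n_trees=config.n_trees, truncation_k=config.truncation_k,
                   shrinkage=config.shrinkage, n_leaves=config.n_leaves,
                   sigma=config.sigma, seed=config.seed)

    @property
    def config(self) -> RankerConfig:
        return RankerConfig(n_trees=self.n_trees, truncation_k=self.truncation_k,
                            shrinkage=self.shrinkage, n_leaves=self.n_leaves,
                            sigma=self.sigma, seed=self.seed)

    def fit(self, X, y, group=None):
        self.config  # validates hyperparameters
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if group is None:
            group = np.zeros(len(y), dtype=np.int64)
        group = np.asarray(group)
        if not (len(X) == len(y) == len(group)):
            raise ValueError("X, y and group must have equal length")
        # Group rows by query, preserving input order within each group.
        _, group_codes = np.unique(group, return_inverse=True)
        group_rows = [np.nonzero(group_codes == g)[0]
                      for g in range(group_codes.max() + 1)]
        # Trainable groups need a positive (IDCG > 0) and a negative.
        trainable = [rows for rows in group_rows
                     if 0 < y[rows].sum() < len(rows)]
        if not trainable:
            raise ValueError("no trainable group with both classes")
        self.base_score_ = 0.0
        self.n_features_in_ = X.shape[1]
        self.trees_ = []
        scores = np.full(len(X), self.base_score_)
        lam = np.zeros(len(X))
        hess = np.zeros(len(X))
        for _ in range(self.n_trees):
            lam[:] = 0.0
            hess[:] = 0.0
            for rows in trainable:
                g_lam, g_hess = compute_lambdas(scores[rows], y[rows],
                                                self.truncation_k, self.sigma)
                lam[rows] = g_lam
                hess[rows] = g_hess
            tree = fit_tree(X, lam, hess, self.n_leaves)
            self.trees_.append(tree)
            scores += self.shrinkage * _tree_predict(tree, X)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "trees_"):
            raise ValueError("ranker is not fitted")
        X = np.asarray(X, dtype=np.float64)
        scores = np.full(len(X), self.base_score_)
        for tree in self.trees_:
            scores += self.shrinkage * _tree_predict(tree, X)
        return scores

    def rank_group(self, query: str, candidates: list[str], X) -> RankedList:
        """Rank one query's candidates; stable ties by input order."""
        scores = self.predict(X)
        order = np.argsort(-scores, kind="stable")
        entries = [(candidates[i], float(scores[i]), rank + 1)
                   for rank, i in enumerate(order)]
        return RankedList(query, entries)

    def feature_usage(self) -> np.ndarray:
        """Number of internal splits on each component feature, over all trees."""
        counts = np.zeros(getattr(self, "n_features_in_", 4), dtype=np.int64)
        for tree in getattr(self, "trees_", []):
            _tree_splits(tree, counts)
        return counts


# Functional wrappers -------------------------------------------------------


def train(groups, config: RankerConfig) -> LambdaMARTRanker:
    """Train from a list of (query_id, X_group, y_group) triples."""
    X = np.vstack([g[1] for g in groups])
    y = np.concatenate([g[2] for g in groups])
    gid = np.concatenate([np.full(len(g[2]), i) for i, g in enumerate(groups)])
    return LambdaMARTRanker.from_config(config).fit(X, y, group=gid)


def predict(model: LambdaMARTRanker, groups) -> list[RankedList]:
    """Rank each (query_id, candidates, X_group) triple."""
    return [model.rank_group(q, cands, X) for q, cands, X in groups]


def feature_usage(model: LambdaMARTRanker) -> np.ndarray:
    return model.feature_usage()


# ---------------------------------------------------------------------------
# Text model format
# ---------------------------------------------------------------------------


def _write_node(fh, node: dict, depth: int) -> None:
    pad = "  " * depth
    if "value" in node:
        fh.write(f"{pad}leaf value={node['value']!r}\n")
    else:
        fh.write(f"{pad}split feature={node['feature']} "
                 f"threshold={node['threshold']!r}\n")
        _write_node(fh, node["left"], depth + 1)
        _write_node(fh, node["right"], depth + 1)


def save_model(model: LambdaMARTRanker, path) -> None:
    """Persist a fitted ranker in the versioned nested-tree text format."""
    with open(path, "w") as fh:
        fh.write(f"format={MODEL_FORMAT} version={MODEL_VERSION}\n")
        for key, value in sorted(model.get_params().items()):
            fh.write(f"param {key}={value!r}\n")
        fh.write(f"n_features={model.n_features_in_}\n")
        fh.write(f"base_score={model.base_score_!r}\n")
        fh.write(f"n_trees_fitted={len(model.trees_)}\n")
        for i, tree in enumerate(model.trees_):
            fh.write(f"tree {i}\n")
            _write_node(fh, tree, 1)


def _parse_nodes(lines: list[str], pos: int, depth: int) -> tuple[dict, int]:
    line = lines[pos]
    body = line.strip()
    if body.startswith("leaf"):
        return {"value": float(body.split("value=")[1])}, pos + 1
    feature = int(body.split("feature=")[1].split()[0])
    threshold = float(body.split("threshold=")[1])
    left, pos = _parse_nodes(lines, pos + 1, depth + 1)
    right, pos = _parse_nodes(lines, pos, depth + 1)
    return {"feature": feature, "threshold": threshold,
            "left": left, "right": right}, pos


def load_model(path) -> LambdaMARTRanker:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = lines[0]
    if not header.startswith(f"format={MODEL_FORMAT}"):
        raise ValueError(f"not a {MODEL_FORMAT} model file")
    params: dict = {}
    pos = 1
    meta: dict = {}
    while pos < len(lines) and not lines[pos].startswith("tree "):
        line = lines[pos]
        if line.startswith("param "):
            key, value = line[len("param "):].split("=", 1)
            params[key] = ast.literal_eval(value)
        else:
            key, value = line.split("=", 1)
            meta[key] = value
        pos += 1
    model = LambdaMARTRanker(**params)
    model.n_features_in_ = int(meta["n_features"])
    model.base_score_ = float(meta["base_score"])
    model.trees_ = []
    while pos < len(lines):
        assert lines[pos].startswith("tree ")
        tree, pos = _parse_nodes(lines, pos + 1, 1)
        model.trees_.append(tree)
    if len(model.trees_) != int(meta["n_trees_fitted"]):
        raise ValueError("model file tree count mismatch")
    return model
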