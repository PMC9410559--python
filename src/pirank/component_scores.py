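"""Per-pair association features and the four component scorers.

A (piRNA p, disease d) pair is described by the concatenation of p's sequence
similarity profile against the reference (benchmark) piRNAs and d's semantic
similarity profile against all diseases:

    F(p, d) = [ S_P(p, :), S_D(d, :) ].

Three supervised classifiers (logistic regression, random forest, linear SVM
with Platt-style probability calibration) are trained on these features over
the benchmark pairs, and a neighbourhood collaborative filter provides a
fourth, purely local score.  Stacked in the fixed order (CF, LR, RF, SVM) the
four scores form the 4-vector Q(p, d) consumed by the listwise ranker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .sequence_similarity import SimilarityMatrix

COMPONENT_NAMES = ("cf", "lr", "rf", "svm")

__all__ = [
    "COMPONENT_NAMES",
    "ClassifierConfig",
    "PairFeatures",
    "build_pair_features",
    "cf_scores",
    "ComponentClassifiers",
    "train_classifiers",
    "score_pairs",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the three supervised component scorers.

    Defaults mirror the published configuration: LR capped at 300 liblinear
    iterations; RF with 80 trees, at most 10 leaf nodes each and 20% of
    features per split; linear-kernel SVM with sigmoid (Platt) calibration.
    """

    lr_max_iter: int = 300
    rf_n_trees: int = 80
    rf_max_leaf_nodes: int = 10
    rf_feature_fraction: float = 0.2
    svm_calibration_folds: int = 3
    n_jobs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr_max_iter, self.rf_n_trees, self.rf_max_leaf_nodes) <= 0:
            raise ValueError("iteration/tree/leaf counts must be positive")
        if not 0.0 < self.rf_feature_fraction <= 1.0:
            raise ValueError("rf_feature_fraction must be in (0, 1]")


@dataclass
class PairFeatures:
    """Feature matrix and labels for an ordered list of (piRNA, disease) pairs.

    ``pirna_idx`` / ``disease_idx`` index into the similarity matrices used to
    build ``X``; every feature lies in [0, 1].
    """

    pirna_idx: np.ndarray
    disease_idx: np.ndarray
    X: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


def build_pair_features(sp_rows: SimilarityMatrix, sd: SimilarityMatrix,
                        pairs: np.ndarray, labels: np.ndarray) -> PairFeatures:
    """Assemble F(p, d) vectors for index ``pairs`` (n, 2).

    ``sp_rows`` holds one row per piRNA (query x reference), ``sd`` one row
    per disease; ``labels`` is the full binary association matrix the pair
    labels are read from.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    p_idx, d_idx = pairs[:, 0], pairs[:, 1]
    if len(p_idx) and p_idx.max() >= sp_rows.shape[0]:
        raise ValueError("pair refers to a piRNA row missing from S_P")
    if len(d_idx) and d_idx.max() >= sd.shape[0]:
        raise ValueError("pair refers to a disease row missing from S_D")
    X = np.hstack([sp_rows.values[p_idx], sd.values[d_idx]])
    y = np.asarray(labels)[p_idx, d_idx].astype(np.int8)
    return PairFeatures(p_idx, d_idx, X, y)


def cf_scores(sp_rows: np.ndarray, bench_labels: np.ndarray,
              pairs: np.ndarray, self_map: np.ndarray | None = None) -> np.ndarray:
    """Neighbourhood collaborative-filtering scores for index ``pairs``.

    V_CF(p, d) = sum_{p' != p} S_P(p, p') * A_bench(p', d)
                 / sum_{p' != p} S_P(p, p'),

    a similarity-weighted average of the benchmark labels of p's sequence
    neighbours, with guilt-by-association semantics.  ``sp_rows`` is
    (n_query, n_reference); ``bench_labels`` is (n_reference, n_disease) and
    must contain benchmark-side positives only.  ``self_map[q]`` gives the
    reference column holding query q itself (or -1), which is excluded so a
    pair's own label never leaks into its score.  Queries whose similarity
    mass is zero score 0.
    """
    sp_rows = np.asarray(sp_rows, dtype=np.float64)
    bench_labels = np.asarray(bench_labels, dtype=np.float64)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if self_map is not None:
        # Zero the query's own column up front so exclusion is exact.
        self_map = np.asarray(self_map, dtype=np.int64)
        owners = np.nonzero(self_map >= 0)[0]
        sp_rows = sp_rows.copy()
        sp_rows[owners, self_map[owners]] = 0.0
    numerator = sp_rows @ bench_labels
    denominator = sp_rows.sum(axis=1)
    scores = np.zeros_like(numerator)
    ok = denominator > 0
    scores[ok] = numerator[ok] / denominator[ok, None]
    return scores[pairs[:, 0], pairs[:, 1]]


@dataclass
class ComponentClassifiers:
    """The three fitted supervised scorers, each emitting P(label = 1)."""

    lr: LogisticRegression
    rf: RandomForestClassifier
    svm: CalibratedClassifierCV

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probabilities, columns in the fixed order (LR, RF, SVM)."""
        return np.column_stack([
            self.lr.predict_proba(X)[:, 1],
            self.rf.predict_proba(X)[:, 1],
            self.svm.predict_proba(X)[:, 1],
        ])


def train_classifiers(X: np.ndarray, y: np.ndarray,
                      config: ClassifierConfig | None = None) -> ComponentClassifiers:
    """Fit LR, RF and calibrated linear SVM on benchmark pair features."""
    config = config or ClassifierConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    lr = LogisticRegression(max_iter=config.lr_max_iter, solver="liblinear",
                            random_state=config.seed)
    rf = RandomForestClassifier(
        n_estimators=config.rf_n_trees,
        max_leaf_nodes=config.rf_max_leaf_nodes,
        max_features=config.rf_feature_fraction,
        n_jobs=config.n_jobs,
        random_state=config.seed,
    )
    svm = CalibratedClassifierCV(
        estimator=LinearSVC(random_state=config.seed),
        method="sigmoid",
        cv=config.svm_calibration_folds,
    )
    lr.fit(X, y)
    rf.fit(X, y)
    svm.fit(X, y)
    return ComponentClassifiers(lr, rf, svm)


def score_pairs(classifiers: ComponentClassifiers, cf: np.ndarray,
                features: PairFeatures) -> np.ndarray:
    """Stacked per-pair score 4-vectors Q(p, d) = (V_CF, V_LR, V_RF, V_SVM)."""
    cf = np.asarray(cf, dtype=np.float64)
    if len(cf) != len(features):
        raise ValueError("CF scores and features cover different pair sets")
    ml = classifiers.score_matrix(features.X)
    return np.column_stack([cf, ml])
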