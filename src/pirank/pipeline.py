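"""End-to-end orchestration: load -> split -> similarities -> component
scores -> listwise ranker -> ranked lists -> evaluation.

Also provides grouped cross-validation and the coordinate-wise ranker
hyperparameter search (one parameter optimized at a time by mean CV AUPR,
in the order trees -> truncation k -> shrinkage -> leaves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .component_scores import (COMPONENT_NAMES, ClassifierConfig, build_pair_features,
                               cf_scores, score_pairs, train_classifiers)
from .data_io import (ASSOCIATION_WISE, PIRNA_WISE, AssociationMatrix, BenchmarkSplit,
                      OntologyDAG, SequenceSet, split_associations, split_pirnas,
                      write_predictions)
from .disease_similarity import disease_similarity_matrix
from .metrics import EvaluationReport, evaluate
from .ranker import (SCENARIO_A_CONFIG, SCENARIO_P_CONFIG, LambdaMARTRanker,
                     RankedList, RankerConfig, save_model)
from .sequence_similarity import (AlignmentScoring, SimilarityMatrix,
                                  cross_similarity, similarity_matrix)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "cross_validate",
    "grid_search",
]

GRID_SEARCH_ORDER = ("n_trees", "truncation_k", "shrinkage", "n_leaves")
#: Initial values held fixed for the parameters not yet optimized.
GRID_SEARCH_START = {"truncation_k": 10, "shrinkage": 0.10, "n_leaves": 10}


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the end-to-end workflow in one place."""

    scenario: str = ASSOCIATION_WISE
    ind_fraction: float = 0.2
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ranker: RankerConfig | None = None
    components: tuple[str, ...] = COMPONENT_NAMES
    k_list: tuple[int, ...] = (5, 10)
    roc_k_list: tuple[int, ...] = (1, 3, 5, 10)
    #: Keep only this fraction of negative benchmark pairs when training the
    #: classifiers (None = no rebalancing, the published protocol).
    negative_subsample: float | None = None
    #: Score benchmark pairs with classifiers trained on the other folds
    #: instead of the in-sample models (the published protocol is in-sample).
    oof_scoring: bool = False
    oof_folds: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in (ASSOCIATION_WISE, PIRNA_WISE):
            raise ValueError(f"unknown scenario: {self.scenario!r}")
        unknown = set(self.components) - set(COMPONENT_NAMES)
        if unknown or not self.components:
            raise ValueError(f"invalid component selection: {self.components}")

    @property
    def ranker_config(self) -> RankerConfig:
        if self.ranker is not None:
            return self.ranker
        return (SCENARIO_A_CONFIG if self.scenario == ASSOCIATION_WISE
                else SCENARIO_P_CONFIG)


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    report: EvaluationReport
    ranked_lists: list[RankedList]
    model: LambdaMARTRanker
    split: BenchmarkSplit
    component_usage: np.ndarray
    n_train_groups: int


def _component_columns(components: tuple[str, ...]) -> list[int]:
    return [COMPONENT_NAMES.index(c) for c in components]


@dataclass
class _StageOutput:
    """Component-score stage products, reusable across ranker configs."""

    q_bench: np.ndarray
    y_bench: np.ndarray
    bench_groups: np.ndarray
    q_ind: np.ndarray
    y_ind: np.ndarray
    ind_groups: np.ndarray
    pirna_ids: list[str]
    disease_ids: list[str]


def _component_stage(seqs: SequenceSet, dag: OntologyDAG, assoc: AssociationMatrix,
                     split: BenchmarkSplit, config: PipelineConfig,
                     sp_full: SimilarityMatrix | None = None,
                     sd: SimilarityMatrix | None = None) -> _StageOutput:
    """Similarities, pair features, component training and stacked scores."""
    n_pi, n_d = assoc.shape
    bench_mask = split.bench_mask(assoc.shape)
    # Benchmark-visible labels: held-out positives are hidden (0).
    a_bench = np.where(bench_mask, assoc.labels, 0).astype(np.int8)
    bench_pi = split.bench_pirnas

    if sp_full is not None:
        sp_ref = SimilarityMatrix(
            list(sp_full.row_ids),
            [sp_full.col_ids[i] for i in bench_pi],
            sp_full.values[:, bench_pi],
        )
    else:
        sp_ref = cross_similarity(seqs, seqs.subset(bench_pi), config.scoring)
    if sd is None:
        sd = disease_similarity_matrix(dag, assoc.disease_ids)

    self_map = np.full(n_pi, -1, dtype=np.int64)
    self_map[bench_pi] = np.arange(len(bench_pi))
    a_ref = a_bench[bench_pi, :]

    feats_bench = build_pair_features(sp_ref, sd, split.bench_pairs, a_bench)
    feats_ind = build_pair_features(sp_ref, sd, split.ind_pairs, assoc.labels)
    cf_bench = cf_scores(sp_ref.values, a_ref, split.bench_pairs, self_map)
    cf_ind = cf_scores(sp_ref.values, a_ref, split.ind_pairs, self_map)

    train_idx = np.arange(len(feats_bench.y))
    if config.negative_subsample is not None:
        rng = np.random.default_rng(config.seed)
        neg = np.nonzero(feats_bench.y == 0)[0]
        keep = rng.choice(neg, size=int(config.negative_subsample * len(neg)),
                          replace=False)
        train_idx = np.sort(np.concatenate(
            [np.nonzero(feats_bench.y == 1)[0], keep]))
    classifiers = train_classifiers(feats_bench.X[train_idx],
                                    feats_bench.y[train_idx], config.classifier)
    cols = _component_columns(config.components)
    q_bench = score_pairs(classifiers, cf_bench, feats_bench)[:, cols]
    if config.oof_scoring:
        q_bench = _oof_bench_scores(feats_bench, cf_bench, config)[:, cols]
    q_ind = score_pairs(classifiers, cf_ind, feats_ind)[:, cols]
    return _StageOutput(
        q_bench=q_bench, y_bench=feats_bench.y, bench_groups=split.bench_pairs[:, 0],
        q_ind=q_ind, y_ind=feats_ind.y, ind_groups=split.ind_pairs[:, 0],
        pirna_ids=list(assoc.pirna_ids), disease_ids=list(assoc.disease_ids),
    )


def _oof_bench_scores(feats_bench, cf_bench, config: PipelineConfig) -> np.ndarray:
    """Benchmark pair scores from classifiers trained on the other folds."""
    n = len(feats_bench.y)
    rng = np.random.default_rng(config.seed)
    fold = rng.integers(0, config.oof_folds, size=n)
    out = np.empty((n, len(COMPONENT_NAMES)))
    for f in range(config.oof_folds):
        held = fold == f
        clf = train_classifiers(feats_bench.X[~held], feats_bench.y[~held],
                                config.classifier)
        out[held, 0] = cf_bench[held]
        out[held, 1:] = clf.score_matrix(feats_bench.X[held])
    return out


def _rank_stage(stage: _StageOutput, split: BenchmarkSplit,
                config: PipelineConfig) -> PipelineResult:
    """Train the ranker on benchmark groups and rank/evaluate the held-out side."""
    model = LambdaMARTRanker.from_config(config.ranker_config)
    model.fit(stage.q_bench, stage.y_bench, group=stage.bench_groups)

    ranked_lists: list[RankedList] = []
    eval_queries = []
    ind_pairs = split.ind_pairs
    for q in np.unique(stage.ind_groups):
        rows = np.nonzero(stage.ind_groups == q)[0]
        candidates = [stage.disease_ids[j] for j in ind_pairs[rows, 1]]
        ranked = model.rank_group(stage.pirna_ids[q], candidates, stage.q_ind[rows])
        ranked_lists.append(ranked)
        scores = model.predict(stage.q_ind[rows])
        eval_queries.append((stage.pirna_ids[q], scores, stage.y_ind[rows]))
    report = evaluate(eval_queries, k_list=config.k_list,
                      roc_k_list=config.roc_k_list)
    n_groups = len({g for g in stage.bench_groups})
    return PipelineResult(report=report, ranked_lists=ranked_lists, model=model,
                          split=split, component_usage=model.feature_usage(),
                          n_train_groups=n_groups)


def _make_split(assoc: AssociationMatrix, config: PipelineConfig) -> BenchmarkSplit:
    if config.scenario == ASSOCIATION_WISE:
        return split_associations(assoc, config.ind_fraction, config.seed)
    return split_pirnas(assoc, config.ind_fraction, config.seed)


def run_pipeline(seqs: SequenceSet, dag: OntologyDAG, assoc: AssociationMatrix,
                 config: PipelineConfig, split: BenchmarkSplit | None = None,
                 sp_full: SimilarityMatrix | None = None,
                 sd: SimilarityMatrix | None = None) -> PipelineResult:
    """Execute the full workflow and evaluate on the independent side.

    ``split`` (and precomputed similarity matrices) may be injected, e.g. by
    cross-validation; otherwise the split is drawn from the config's scenario,
    fraction and seed.
    """
    if split is None:
        split = _make_split(assoc, config)
    stage = _component_stage(seqs, dag, assoc, split, config, sp_full, sd)
    result = _rank_stage(stage, split, config)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_predictions(out / "predictions.tsv", result.ranked_lists)
        result.report.write_tsv(out / "report.tsv")
        save_model(result.model, out / "model.txt")
        with open(out / "manifest.txt", "w") as fh:
            fh.write(f"scenario={config.scenario}\n")
            fh.write(f"ind_fraction={config.ind_fraction}\n")
            fh.write(f"seed={config.seed}\n")
            fh.write(f"components={','.join(config.components)}\n")
            fh.write(f"ranker={config.ranker_config}\n")
    return result


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _cv_splits(assoc: AssociationMatrix, n_folds: int, scenario: str,
               seed: int) -> list[BenchmarkSplit]:
    rng = np.random.default_rng(seed)
    n_pi, n_d = assoc.shape
    splits = []
    if scenario == ASSOCIATION_WISE:
        all_pairs = np.argwhere(np.ones(assoc.shape, dtype=bool))
        perm = rng.permutation(len(all_pairs))
        folds = np.array_split(perm, n_folds)
        for fold in folds:
            mask = np.zeros(len(all_pairs), dtype=bool)
            mask[fold] = True
            splits.append(BenchmarkSplit(ASSOCIATION_WISE, all_pairs[~mask],
                                         all_pairs[mask], seed))
    else:
        perm = rng.permutation(n_pi)
        folds = np.array_split(perm, n_folds)
        cols = np.arange(n_d)
        for fold in folds:
            flag = np.zeros(n_pi, dtype=bool)
            flag[fold] = True
            ind_rows = np.nonzero(flag)[0]
            bench_rows = np.nonzero(~flag)[0]
            ind_pairs = np.column_stack(
                [np.repeat(ind_rows, n_d), np.tile(cols, len(ind_rows))])
            bench_pairs = np.column_stack(
                [np.repeat(bench_rows, n_d), np.tile(cols, len(bench_rows))])
            splits.append(BenchmarkSplit(PIRNA_WISE, bench_pairs, ind_pairs, seed))
    return splits


def cross_validate(seqs: SequenceSet, dag: OntologyDAG, assoc: AssociationMatrix,
                   config: PipelineConfig, n_folds: int = 5) -> list[EvaluationReport]:
    """K-fold CV with the full stage stack retrained per fold.

    Folds partition pairs (association-wise) or piRNAs (pirna-wise).  A fold
    whose training side has a single label class is skipped with a warning.
    Sequence and disease similarities are computed once and shared.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    sp_full = similarity_matrix(seqs, config.scoring)
    sd = disease_similarity_matrix(dag, assoc.disease_ids)
    reports = []
    for split in _cv_splits(assoc, n_folds, config.scenario, config.seed):
        y_bench = assoc.labels[split.bench_pairs[:, 0], split.bench_pairs[:, 1]]
        if len(np.unique(y_bench)) < 2:
            warnings.warn("skipping fold with single-class training labels")
            continue
        result = run_pipeline(seqs, dag, assoc, config, split=split,
                              sp_full=sp_full, sd=sd)
        reports.append(result.report)
    return reports


# ---------------------------------------------------------------------------
# Coordinate-wise hyperparameter search
# ---------------------------------------------------------------------------


def grid_search(seqs: SequenceSet, dag: OntologyDAG, assoc: AssociationMatrix,
                grids: dict[str, list], config: PipelineConfig,
                n_folds: int = 5) -> tuple[RankerConfig, list[dict]]:
    """Coordinate-wise ranker parameter search by mean CV AUPR.

    One parameter at a time is optimized over its grid while the other three
    stay fixed, in the order trees -> truncation k -> shrinkage -> leaves;
    parameters not yet visited hold their starting values (k=10,
    shrinkage=0.10, leaves=10).  The trace records every evaluated point, so
    its length is the *sum* of the grid sizes, not their product.  Component
    scores per fold are computed once and reused for every candidate.
    """
    if not grids:
        raise ValueError("empty grid")
    sp_full = similarity_matrix(seqs, config.scoring)
    sd = disease_similarity_matrix(dag, assoc.disease_ids)
    stages = []
    for split in _cv_splits(assoc, n_folds, config.scenario, config.seed):
        stages.append((_component_stage(seqs, dag, assoc, split, config,
                                        sp_full, sd), split))

    def mean_aupr(rconf: RankerConfig) -> float:
        values = []
        for stage, split in stages:
            result = _rank_stage(stage, split, replace_ranker(config, rconf))
            values.append(result.report.macro["aupr"])
        return float(np.mean(values))

    def replace_ranker(cfg: PipelineConfig, rconf: RankerConfig) -> PipelineConfig:
        return replace(cfg, ranker=rconf)

    start_trees = grids.get("n_trees", [config.ranker_config.n_trees])[0]
    current = RankerConfig(n_trees=start_trees, **GRID_SEARCH_START)
    trace: list[dict] = []
    for param in GRID_SEARCH_ORDER:
        if param not in grids:
            continue
        best_value, best_score = None, -np.inf
        for value in grids[param]:
            candidate = replace(current, **{param: value})
            score = mean_aupr(candidate)
            trace.append({"param": param, "value": value,
                          "config": candidate, "mean_aupr": score})
            if score > best_score:
                best_value, best_score = value, score
        current = replace(current, **{param: best_value})
    return current, trace
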