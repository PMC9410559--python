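# Methods

## Problem setting

`pirank` ranks candidate diseases for query piRNAs from three inputs: piRNA
sequences (FASTA), a disease ontology given as is_a parent→child edges (OBO
or edge TSV), and a binary piRNA×disease association matrix in which 1 marks
an experimentally known association and 0 an unknown pair (treated as
negative for training). Two evaluation scenarios are supported:

* **association-wise** — a fraction of *pairs* (positives and unknowns
  sampled independently, `floor(fraction · N)` of each) is held out; every
  piRNA can appear on both sides. This models completing the association
  matrix for known piRNAs.
* **pirna-wise (cold start)** — a fraction of *piRNAs* is held out with all
  their pairs, so held-out queries are entirely unseen during training.

Held-out positives are invisible to every training stage: the
benchmark-visible label matrix zeroes them before the collaborative filter
or any classifier sees it.

## Similarities

**Sequences.** Exact Smith–Waterman local alignment with a linear
(per-symbol) gap penalty; the similarity is the raw score normalized by the
geometric mean of the two self-alignment scores, which lands in [0, 1] with
1 on the diagonal. Scoring defaults are match +2, mismatch −1, gap −1 —
deliberately simple, with strictly positive self-scores, and configurable.
An affine gap model is intentionally out of scope: at 24–31 nt the linear
model is standard and exact DP over all pairs is cheap (an all-against-all
matrix for a few hundred sequences takes seconds via the numba kernel; the
plain-Python DP is the readable reference path and is tested against a
brute-force alignment enumerator).

**Diseases.** Wang-method semantic similarity over the ontology DAG. Each
term contributes 1.0 to itself and `max over children-on-path of 0.5 ×
child's value` to each ancestor; the similarity of two terms is their shared
contribution mass divided by total mass. The 0.5 decay is exposed as a
constant. In the max, children of an ancestor are restricted to those on a
path to the target term — other children have no defined contribution.
Multi-rooted ontologies are allowed; terms with disjoint ancestry score 0.

## Component scores

A pair (p, d) is featurized as `F(p, d) = [S_P(p, reference piRNAs),
S_D(d, all diseases)]`. The reference set is the benchmark piRNAs in both
scenarios, so a newly detected piRNA's features are computable. Four
scorers produce the stacked vector `Q(p, d)` in the fixed order (CF, LR,
RF, SVM):

* **Collaborative filter** — `V_CF(p, d) = Σ_{p'≠p} S_P(p,p')·A(p',d) /
  Σ_{p'≠p} S_P(p,p')` over benchmark piRNAs, 0 when the similarity mass is
  0. The query's own column is excluded, so a training pair never sees its
  own label (verified by a leakage test).
* **Logistic regression** — liblinear, L2, 300-iteration cap.
* **Random forest** — 80 trees, ≤ 10 leaf nodes each, 20% of features per
  split. `n_jobs` defaults to 1 for run-to-run reproducibility.
* **Linear SVM** — `LinearSVC` with sigmoid (Platt) probability calibration
  (3-fold). This is the same linear-kernel-plus-Platt model family as
  `SVC(kernel="linear", probability=True)` but trains orders of magnitude
  faster at tens of thousands of pairs.

Classifiers train on *all* benchmark pairs with no class rebalancing (an
optional negative-subsampling flag exists, off by default). Benchmark pairs
are scored by the same models that were trained on them — by design, so the
ranker's training inputs match the published protocol; an out-of-fold
scoring mode is available for leakage-sensitive analyses but is not the
default.

## LambdaMART ranker

Candidates of one query form a group. Per boosting round, for each group
with at least one positive and one negative, every (positive i, negative j)
pair contributes

    rho      = 1 / (1 + exp(sigma (s_i − s_j)))
    λ_i     += sigma · rho · |ΔNDCG@k(i,j)|,   λ_j −= the same
    w_i, w_j += sigma² · rho (1 − rho) · |ΔNDCG@k(i,j)|

where `|ΔNDCG@k|` is the NDCG@k change from swapping i and j in the current
score-sorted order (stable ties by input index; gain 2^rel − 1, discount
1/log2(rank+1), zero past k). One regression tree per round is fitted on
the pooled 4-dimensional score vectors with greedy *unweighted*
variance-reduction splits and Newton leaf values `Σλ / (Σw + 1e-9)`, grown
best-first to at most `n_leaves` leaves, then added with a constant
shrinkage. Groups without positives are excluded from training (their ideal
DCG is undefined) but remain rankable. Training is deterministic — there is
no row or feature subsampling over only four features — and the seed is
reserved for future stochastic options.

Unweighted split gain (rather than the Newton gain `G²/H`) is a deliberate
choice: it guarantees that constant lambda targets always produce a
single-leaf tree, which the Newton gain does not when hessian weights vary.

Scenario defaults follow the tuned optima (trees, k, shrinkage, leaves):
(120, 14, 0.22, 3) for the association-wise scenario and (30, 15, 0.10, 29)
for cold start. The coordinate-wise search that produced such optima is
implemented in `pipeline.grid_search`: one parameter at a time is optimized
by mean cross-validation AUPR in the order trees → k → shrinkage → leaves,
the others initially fixed at (k=10, shrinkage=0.10, leaves=10).

Models persist to a versioned plain-text format: a header with the
hyperparameters, then per-tree nested `split feature=… threshold=…` /
`leaf value=…` records indented by depth. Floats are written with `repr`,
so reload is bit-exact.

## Evaluation

All metrics are computed per query over that query's evaluation pairs only
and macro-averaged across queries. Queries with no positive are skipped and
counted; AUC additionally requires a negative. Conventions: NDCG returns 0
when the ideal DCG is 0; MAP is non-interpolated average precision of the
discrete ranking; AUPR applies the same average precision to the
score-sorted ranking (identical to MAP when scores are distinct); AUC is
the Mann–Whitney statistic with half credit for ties; ROCk is the truncated
ROC score used in ranked homolog retrieval — the mean number of true
positives preceding each of the first k false positives, normalized by
k·(total positives), with k truncated to the available negatives and a
vacuous 1.0 when there are none. Ties elsewhere keep candidate input order
(stable sorts throughout). A pooled (non-macro) evaluation can be obtained
by passing a single merged query.

## Synthetic benchmarks

The generator plants exactly the structure the method exploits, nothing
else. Sequences come in mutation-derived families: one random 24–31 nt seed
per family, members are per-position substitution mutants (rate 0.08 by
default; optional deletions for harder fixtures). The ontology is a rooted
tree (default depth 2 with branching 5×4 → 20 leaf diseases in 5 subtree
clusters). Each family maps round-robin to one cluster; a pair is positive
with probability `p_in = 0.7` inside the family's cluster and
`p_out = 0.02` outside. All stages draw from per-stage seeded streams, so
every artifact is byte-reproducible from the config.

Defaults (30 families × 10 members = 300 piRNAs, 20 diseases) keep the full
pipeline under half a minute per run while leaving the task non-trivial:
within-family sequence similarity exceeds cross-family similarity for ≥95%
of sampled pairs, but the association noise bounds attainable performance
(see limitations). Setting `p_in = p_out` severs similarity from labels and
serves as a negative control; 0.35 is used in the acceptance script so that
queries keep enough positives for per-query AUC to be defined.

What the generator does **not** emulate: real piRNA cluster genomics,
ping-pong signatures, the skewed degree distribution of curated databases,
ontology terms with multiple parents, or disease-specific prevalence.
Passing the synthetic suite therefore demonstrates that the machinery
recovers a planted sequence-family → disease-cluster signal, not that the
published benchmark figures transfer.

## Numerical and degenerate-input choices

* Normalized similarities are clipped to [0, 1] against rounding; symmetric
  matrices are computed on the upper triangle and mirrored, so symmetry is
  exact.
* `SW(a,b) = 0` yields similarity 0; zero CF similarity mass yields score 0.
* Lambda computation returns zeros for single-class groups; `n_trees = 0`
  yields a constant-score model that ranks by input order.
* Leaf values use ε = 1e-9 in the Newton denominator.
* Split sampling uses `floor(fraction · N)` (so a 0.2 fraction of 5002
  positives holds out exactly 1000); sampling is uniform without
  replacement from a seeded `numpy` generator.

## Known limitations

* On the default synthetic benchmark the association-wise macro AUC is
  noise-bounded: scoring pairs by the *true* planted cluster membership
  achieves only ≈ 0.92 because in-cluster positives and negatives are
  exchangeable and out-of-cluster positives are pure noise. The trained
  pipeline lands ≈ 0.89, i.e. within ~0.03 of that ceiling; comparisons
  against an external gradient-boosting ranker on identical stacked scores
  show the residual gap is not specific to this LambdaMART implementation.
* The collaborative filter averages over *all* benchmark neighbours; with a
  high similarity floor between unrelated short sequences, global disease
  popularity dilutes the family signal. Sharper neighbourhood weighting
  would change the published formula and is intentionally not done.
* Linear components (LR, SVM) produce a query-independent disease ranking
  within any one query group, since only the `S_D` block of the feature
  vector varies across a query's candidates. They contribute through the
  ranker's interactions with CF/RF rather than on their own.
* The SVM component is a calibrated `LinearSVC`, not libsvm's `SVC`; decision
  values can differ slightly from the reference implementation.
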