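# pirank

Learning-to-rank prediction of piRNA–disease associations.

Piwi-interacting RNAs (piRNAs, 24–31 nt small non-coding RNAs) are emerging
disease biomarkers, but experimentally mapping which diseases a piRNA is
involved in is slow and expensive. `pirank` treats the problem as a retrieval
task: each query piRNA is a "query", candidate diseases are "documents", and
a listwise ranker orders the diseases by predicted association strength. The
package handles both practical settings:

* **missing associations** — the query piRNA already has some known disease
  links and we rank its remaining candidate pairs;
* **cold start** — the query piRNA is newly detected and appears nowhere in
  the training associations.

It is aimed at computational biologists building or benchmarking
ncRNA–disease association predictors.

## Method

Given piRNA sequences, a disease ontology (is_a DAG) and a sparse binary
association matrix `A`:

1. **Sequence similarity.** `S_P(p_i, p_j) = SW(p_i, p_j) / sqrt(SW(p_i,p_i)
   · SW(p_j,p_j))`, where `SW` is the exact Smith–Waterman local-alignment
   score with a linear gap model (defaults match +2 / mismatch −1 / gap −1).
2. **Disease semantic similarity.** Wang-style ontology similarity: each term
   `n` spreads a semantic contribution `S_n(i)` over itself (1.0) and its
   ancestors (decay 0.5 per edge, max over paths), and
   `S_D(m, n) = Σ_{i∈T_m∩T_n}(S_m(i)+S_n(i)) / (Σ S_m + Σ S_n)`.
3. **Pair features.** `F(p, d) = [S_P(p, :), S_D(d, :)]` over the benchmark
   (training-side) reference piRNAs and all diseases.
4. **Component scores.** Four per-pair scorers stacked as
   `Q(p, d) = (V_CF, V_LR, V_RF, V_SVM)`: a neighbourhood collaborative
   filter (similarity-weighted average of neighbours' labels, self-excluded),
   logistic regression, a random forest and a calibrated linear SVM, all
   trained on benchmark pairs.
5. **Listwise ranking.** A LambdaMART model — gradient-boosted regression
   trees driven by lambda gradients weighted by `|ΔNDCG@k|` — is trained on
   the per-query groups of `Q` vectors and used to rank each query's
   candidate diseases.

Evaluation reports macro-averaged (per query piRNA) AUC, AUPR, NDCG@k, MAP
and the truncated ROC score ROCk.

## Worked example

Generate a synthetic benchmark (sequence families wired to disease clusters)
and run the cold-start scenario end to end:

```sh
pirank simulate --out-dir bench --n-families 10 --members-per-family 6 --seed 4
pirank run --fasta bench/sequences.fasta --ontology bench/ontology.tsv \
    --associations bench/associations.tsv --scenario pirna-wise \
    --seed 1 --out-dir out
```

This holds out 20% of the piRNAs as "newly detected", trains the component
scorers and the ranker on the rest, ranks the held-out queries' candidate
diseases, and prints the macro-averaged report:

```
auc	0.840057
aupr	0.607959
map	0.607959
ndcg@5	0.614713
ndcg@10	0.705792
roc@1	0.358333
roc@3	0.504167
roc@5	0.587500
roc@10	0.729167
n_queries_evaluated	12
n_queries_skipped	0
```

AUC 0.84 means a held-out piRNA's true disease outranks a random non-disease
84% of the time; NDCG@5 0.61 measures how much of the attainable top-5 gain
the ranking realises. `out/predictions.tsv` holds the ranked lists
(pirna_id, disease_id, score, rank, rank 1 = best):

```
pirna_id	disease_id	score	rank
fam00_m01	t.00.02	2.9706551151156524	1
fam00_m01	t.00.00	2.4132905231122908	2
fam00_m01	t.00.01	1.1940684704842228	3
```

`out/model.txt` stores the fitted ranker in a human-readable nested-tree
text format. Other subcommands (`similarity`, `split`, `components`,
`train`, `predict`, `evaluate`, `cv`, `gridsearch`) expose the individual
stages; the library API (`pirank.run_pipeline`, `pirank.LambdaMARTRanker`,
…) mirrors scikit-learn conventions (`fit` / `predict`, `get_params`).

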