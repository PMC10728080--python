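# panemt

Pan-cancer EMT subtyping: a tested, reusable implementation of a
signature-driven pipeline that stratifies tumors by epithelial–mesenchymal
transition (EMT) activity into four subtypes — EMT^low, EMT^mid,
EMT^high-NOS and EMT^high-AKT — and characterizes them with multi-omics and
survival statistics.

It is written for computational biologists who want to apply (or stress-test)
this kind of stratification on their own cohorts, or to audit each stage
against planted ground truth.

## What it computes

1. **Signature derivation** (`panemt.build_signature`): starting from a
   positively-oriented EMT gene set, subtract negatively-oriented sets, keep
   the top ⌈⅔·n⌉ of genes by protein-interaction degree and, separately, by
   co-expression score, and intersect the two lists into a core signature.
2. **Single-sample enrichment** (`panemt.ssgsea_scores`): for sample *j* and
   gene set *S*, with genes ranked descending by expression and ascending
   rank values *r* as weights,

   ES(S, j) = Σᵢ [ Σ_{g∈S, pos(g)≤i} r_g^α / Σ_{g∈S} r_g^α − |{g∉S, pos(g)≤i}| / (N−|S|) ],  α = 0.25.

   Scores depend only on within-sample ranks, so they are invariant to any
   monotone transform of a sample's expression.
3. **Consensus clustering** (`panemt.run_consensus`): repeated k-means
   (Euclidean, k-means++) on 80% subsamples; consensus(i,j) = co-cluster
   count / co-sample count; cluster number read off the CDF/delta-area
   curve; final labels by average-linkage clustering of 1 − consensus.
4. **Centroid classification** (`panemt.assign_by_centroid`): an external
   sample x, scaled gene-wise with the *reference* cohort statistics, is
   assigned to the subtype c minimizing d_c = √Σᵢ (xᵢ − centroid_{c,i})²;
   a KNN vote (`assign_by_knn`) is the alternative for cross-species data.
   ComBat-style empirical-Bayes batch adjustment (`combat_adjust`) merges
   cohorts first.
5. **Multi-omics regulator screens** (`panemt.screens`): mutation frequency
   vs a genome-wide baseline (freq > 3%, fold > 1.5), expression–copy-number
   correlation (r > 0.3, altered fraction > 30%, BH FDR < 0.05),
   expression–methylation anti-correlation on the most-methylated probe
   (r < −0.3, FDR < 0.05), and per-cluster driver-event enrichment
   (Fisher/chi-square, adj-p < 0.05, fold > 1.5).
6. **Cohort statistics** (`panemt.stats`): cancer-type-balanced resampling
   validation (10 patients per cancer per cluster, 100 iterations),
   category-count normalization to 100 per cancer type, univariate Cox
   (Newton–Raphson, Breslow ties), Kaplan-Meier medians with log-rank
   tests, and the tumor-purity transform
   purity = cos(0.6049872018 + 0.0001467884 · estimatescore).
7. **Synthetic cohorts** (`panemt.simulate_cohort`): planted-truth
   pan-cancer cohorts (cancer-type batch structure, four planted subtypes,
   omics-coupled regulator genes, score-dependent survival) that make every
   stage testable without downloads. See `docs/methods.md` for the model.

## Worked example

```python
import panemt
from sklearn.metrics import adjusted_rand_score

cohort = panemt.simulate_cohort(panemt.SimulationConfig(seed=0))
scores = panemt.ssgsea_scores(
    cohort.expression,
    panemt.GeneSetCollection({"EMTCG": cohort.signature["EMTCG"]}),
).data.loc["EMTCG"]

scaled = panemt.scale_genes(cohort.expression.subset_genes(cohort.signature["EMTCG"]))
run = panemt.run_consensus(scaled, range(2, 7), reps=100, seed=1)
metrics = panemt.consensus_metrics(run)
print(metrics.round(3).to_string(index=False))
print("suggested K:", panemt.suggest_k(metrics))
model = panemt.final_clusters(run, 4)
print("cluster sizes:", model.labels.value_counts().sort_index().to_dict())
print("ARI vs planted truth:",
      round(adjusted_rand_score(cohort.true_labels[model.labels.index], model.labels), 3))

clin = cohort.clinical.data
res = panemt.cox_univariate(clin["survival_time"], clin["event"], clin["emt_score"])
print(f"Cox: HR={res.hr:.3f} (beta={res.beta:.3f}, se={res.se:.3f}, p={res.p_value:.2e})")
```

prints

```
 K  area  delta_area
 2 0.500       0.500
 3 0.609       0.217
 4 0.732       0.202
 5 0.784       0.071
 6 0.830       0.059
suggested K: 4
cluster sizes: {1: 159, 2: 291, 3: 195, 4: 315}
ARI vs planted truth: 0.976
Cox: HR=1.761 (beta=0.566, se=0.043, p=2.27e-39)
```

Reading: the area under the consensus CDF stops gaining sharply after K=4
(delta-area 0.202 → 0.071), the elbow heuristic therefore suggests four
clusters; the recovered partition agrees with the planted subtypes at ARI
0.976; and the per-sd EMT-score hazard ratio of 1.76 recovers the planted
log-hazard of 0.5 (β̂ = 0.566 ± 0.043) on this 960-sample cohort.

The same pipeline is available from the shell:

```bash
panemt simulate --seed 0 --out-dir cohort/
panemt score --expr cohort/expression.tsv --sets cohort/signature.gmt --out scores.tsv
panemt cluster --expr cohort/expression.tsv --signature cohort/signature.gmt \
    --kmin 2 --kmax 6 --seed 1 --k 4 --out-dir clusters/
```

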