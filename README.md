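# flaresig

Kidney biopsies taken at a lupus-nephritis (LN) flare carry a molecular
signature that histology misses: the expression profile of immune-response
genes in the tissue differs between patients who will and will not respond
to standard induction therapy. `flaresig` implements the full analysis
pipeline for such studies — digital-counting (nCounter-style) panels of a
few hundred immune genes measured on small groups of FFPE biopsies — as a
tested, reusable Python package:

1. **Normalisation** — per-lane scale factors from the geometric mean of
   the positive spike-in titration ladder; exclusion of genes not at least
   2 SD above the mean of the negative-control probes; `log2(x + 1)`; and
   rank-mean quantile normalisation across assays.
2. **Batch standardisation** — the study design runs assays in two batches
   with the *same control samples in both*; those shared controls anchor a
   per-gene additive log2 offset estimate, subtracted before the quantile
   step (batch can alternatively enter the linear model as a covariate).
3. **Moderated differential expression** — per-gene OLS of log2 expression
   on response group (control / complete / partial / no response), with
   empirical-Bayes variance smoothing: sample variances s²_g (df d) are
   shrunk towards a scaled-inverse-χ² prior (d₀, s₀²) estimated by
   log-variance moment matching, giving the posterior
   s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) and a moderated t with d + d₀ df.
   Multiple testing uses expected-false-positive control, α = k/m (e.g.
   4 expected false positives among 400 genes ⇒ α = 0.01); a call further
   requires at least a two-fold change.
4. **Signature partitioning** — exact Venn decomposition of the per-group
   significant-gene sets (shared core vs group-unique transcripts), plus
   RT-PCR direction-concordance checks (fold = 2^(−ΔΔCt)).
5. **PCA profiling** — principal components of the assay-by-gene matrix
   with the top-20 genes by absolute PC1 loading, and a silhouette-based
   cluster-separation diagnostic.
6. **Gene-set enrichment** — one-sided Fisher/hypergeometric
   overrepresentation against a stated background (reported as −log₁₀ p)
   and, for signed gene sets, the activation z-score
   z = (n_consistent − n_inconsistent)/√N with an activated/suppressed call
   at |z| ≥ 2.
7. **Clinical statistics** — Welch t, one-way ANOVA or exact Wilcoxon
   rank-sum with Bonferroni correction, and two-sided Fisher's exact test
   for categorical variables.

Because raw data for studies of this kind are often not deposited, the
package ships a first-class **synthetic-study generator**
(`flaresig.simulate`) that emulates the design — 511 endogenous + 6
positive + 6 negative probes, groups of 4 controls / 5 CR / 10 PR / 4 NR,
two assay batches (9 + 10 lanes) with controls in both, negative-binomial
counting noise, log-normal lane factors, planted group signatures — and
records every planted quantity so each stage is tested against ground
truth.

## Worked example

```python
from flaresig import (ExpressionLinearModel, apply_quantile, enfp_alpha,
                      normalize_pipeline, run_pca, top_loading_genes,
                      venn_partition)
from flaresig.batch import correct_batches, estimate_batch_offsets
from flaresig.simulate import SimConfig, simulate_study

study = simulate_study(SimConfig(seed=7))
expr = normalize_pipeline(study.counts, quantile=False)
offsets = estimate_batch_offsets(expr, study.meta)     # anchored on controls
expr = apply_quantile(correct_batches(expr, offsets, study.meta))

results = ExpressionLinearModel(expr, study.meta, include_batch=False).fit()
alpha = enfp_alpha(len(expr.gene_ids), 4)              # 4 / 400 = 0.01
print(results.summary(alpha=alpha))
```

```
Moderated linear model of log2 expression
================================================
genes: 400    assays: 27
design columns: Intercept, group_CR, group_NR, group_PR
residual df: 23    prior df d0: 76.7    prior variance s0^2: 0.07078
gate: fold >= 2 (or <= 0.5) and p < 0.01
------------------------------------------------
      CR-control:    19 significant genes
      NR-control:    26 significant genes
      PR-control:    26 significant genes
```

400 of the 511 endogenous probes cleared the 2-SD background filter (the
other 111 are simulated at background level). The moderated fits pooled the
per-gene variances towards s₀² ≈ 0.071 with ≈ 77 prior df, and at the
α = 0.01 / two-fold gate each LN group shows 19–26 differentially expressed
genes relative to normal kidney. Partitioning those sets,

```python
sets = {g: results.significant(f"{g}-control", alpha=alpha)
        for g in ("CR", "PR", "NR")}
for region, genes in sorted(venn_partition(sets).items()):
    print(f"{region:>16}: {len(genes)} genes")
```

```
        CR∩PR∩NR: 19 genes
         NR only: 7 genes
         PR only: 7 genes
```

recovers the planted structure: a 19-gene core shared by every response
group plus group-unique signatures (the weaker CR-unique effects, planted
near the two-fold gate, are only partially recalled — the expected
behaviour at n = 5). Finally,

```python
pca = run_pca(expr)
print("PC1 variance fraction: %.3f" % pca.variance_fraction[0])
print(top_loading_genes(pca).head(5).to_string(index=False))
```

```
PC1 variance fraction: 0.357
    gene   loading  abs_loading
GENE_017  0.281643     0.281643
GENE_007 -0.243733     0.243733
GENE_003 -0.226597     0.226597
GENE_004 -0.224207     0.224207
GENE_018  0.217871     0.217871
```

PC1 carries ~36% of the variance and its top loadings are dominated by the
planted core genes (`GENE_001`–`GENE_019`), i.e. the genes that drive group
clustering.

The same pipeline is available from the shell:

```sh
flaresig simulate --seed 7 --out fixture/
flaresig normalize --counts fixture/counts.tsv --out expr.tsv
flaresig batch-correct --expr expr.tsv --meta fixture/meta.tsv --out expr_bc.tsv
flaresig de --expr expr_bc.tsv --meta fixture/meta.tsv --out de.tsv
flaresig run --config run.yaml        # one-command orchestration
```

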