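# deges

Multi-group RNA-seq differential expression with iterative
DEG-elimination (DEGES) normalization.

## The problem

Differential-expression (DE) analysis of RNA-seq count data starts from
a gene × sample count matrix and a two-step pipeline: compute
per-sample normalization factors (*X*), then test each gene (*Y*).
Scaling-factor methods such as TMM or median-of-ratios assume that most
genes are not differentially expressed between samples.  In a
multi-group design (G1 vs. G2 vs. G3) this assumption breaks when the
differentially expressed genes (DEGs) are concentrated in one group:
with proportions such as (P<sub>G1</sub>, P<sub>G2</sub>, P<sub>G3</sub>) =
(0.8, 0.1, 0.1), the up-regulated genes inflate the library composition
of G1, the factors absorb part of the DE signal, and ranking accuracy
drops.

The DEG elimination strategy (DEGES) addresses this with the pipeline
*X*-(*Y*-*X*)<sub>n</sub>-*Z*: normalize on all genes, flag potential
DEGs with a multi-group test, recompute the factors on the non-flagged
genes only, iterate *n* times (default 3), and finally identify DEGs
with test *Z* under the cleaned-up factors.  This package implements
that pipeline for designs with three or more groups, together with the
negative-binomial (NB) simulator and the AUC evaluation harness used to
validate it.

## The model

Counts follow a negative binomial with variance
*V* = *μ* + *Φμ*²,
fitted per gene as a one-way NB GLM with log link and offsets
log(effective library size), where effective library size =
raw library size × normalization factor.  The full model fits one mean
per group, the null model one overall mean; genes are ranked by the
ANOVA-like likelihood-ratio p-value (χ² with G − 1 df), adjusted by
Benjamini–Hochberg.  Dispersion *Φ* is estimated by maximizing the
Cox–Reid adjusted profile likelihood — a common value shared by all
genes, shrunk per gene by weighted-likelihood (tagwise) estimation.
Designs without replicates use blind estimation (group labels ignored),
which DE inflates, making the no-replicate test deliberately
conservative.

Pipelines are named by letter codes: `E-E` (TMM + NB-LRT, no
iteration), `EEE-E` (the same with three DEG-elimination iterations),
`DED-E`, `SSS-S`, ... where `E` selects TMM normalization and `D`/`S`
median-of-ratios.

## Worked example

Simulate biased three-group data (10,000 genes, 25% DEGs, 80% of them
up-regulated in G1, three replicates per group, four-fold DE) and
compare the plain pipeline with its DEGES counterpart:

```python
from deges import (SimulationConfig, simulate_counts, resolve_pipeline_name,
                   run_deges, auc_from_ranking)

cfg = SimulationConfig(
    n_gene=10000, p_deg=0.25, group_sizes=(3, 3, 3),
    deg_proportions=(0.8, 0.1, 0.1), seed=1,
)
counts, truth, design = simulate_counts(cfg)

for code in ("E-E", "EEE-E"):
    rec = run_deges(counts, design, resolve_pipeline_name(code), seed=1)
    roc = auc_from_ranking(rec.final_result.p_value, truth)
    print(f"{code:6s} AUC = {100 * roc.auc:.2f}%")
    for i, it in enumerate(rec.iterations):
        print(f"       iteration {i+1}: estimated P_DEG = "
              f"{100 * it.estimated_pdeg:.1f}% ({it.flag_source})")
```

prints

```
E-E    AUC = 97.78%
EEE-E  AUC = 98.72%
       iteration 1: estimated P_DEG = 26.9% (fdr)
       iteration 2: estimated P_DEG = 26.8% (fdr)
       iteration 3: estimated P_DEG = 26.8% (fdr)
```

The AUC measures how well the p-value ranking separates the 2,500 true
DEGs from the rest (1.0 = perfect, 0.5 = random).  Under this biased
condition the iterative pipeline gains roughly one AUC point; each
iteration estimates P_DEG close to the true 25% and removes those genes
before recomputing the TMM factors.  With equal DEG proportions
(1/3, 1/3, 1/3) the two pipelines tie, as they should.

The same run is available from the shell:

```sh
deges simulate --n-gene 10000 --p-deg 0.25 --deg-proportions 0.8,0.1,0.1 \
      --seed 1 --out sim/
deges deges sim/counts.tsv sim/design.tsv --pipeline EEE-E --seed 1 --out run
deges evaluate-auc run.results.tsv sim/truth.tsv
```

Other subcommands: `normalize`, `test`, `study`, `cluster`,
`classify-patterns`, `collapse`.

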