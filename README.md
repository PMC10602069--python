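# bfhde

Bayesian–frequentist hybrid inference for pseudo-bulk single-cell
differential expression.

## The problem

Pseudo-bulk differential expression — summarizing single-cell RNA-seq
counts to one value per donor per gene, then regressing on phenotype —
is the standard way to respect donor-level variability, but cohorts of a
few dozen donors leave it underpowered. `bfhde` implements a hybrid
estimation framework that recovers power from two sources:

1. **Probability-weighted aggregation.** Instead of averaging only the
   cells hard-called as the target cell type, every cell contributes to the
   donor summary with weight equal to its classifier probability of being
   that type, so no information is discarded at an arbitrary call
   threshold.
2. **Informative priors from bulk RNA-seq.** The covariate-adjusted
   case/control difference estimated per gene in a (cheap, large) bulk
   cohort centers a normal prior on the group coefficient of the
   single-cell model.

It is aimed at statisticians and computational biologists running
donor-level DE on annotated single-cell data with an external cell-type
classifier and an auxiliary bulk cohort.

## The model

Per gene, with one observation per donor,

```
Y = β₀ + β₁·group + β₂·x2 + ε,     ε ~ N(0, σ²I)
```

where `Y[d]` is the probability-weighted mean expression
`Σᵢ wᵢ c_i / Σᵢ wᵢ` over donor *d*'s cells, `group` is the binary
phenotype, and `x2[d] = −log( mean cell-type probability of donor d )`
adjusts for how confidently the donor's cells were assigned. Three
estimators of `β = (β₀, β₁, β₂)` are provided:

* **frequentist** — OLS: `β̂ = (XᵀX)⁻¹XᵀY`, `Σ̂ = (XᵀX)⁻¹σ²`;
* **bayes** — conjugate posterior under `β ~ N(μ, diag(τ²))`, posterior
  precision `diag(1/τ²) + XᵀX/σ²` (flat priors recover OLS exactly);
* **hybrid** — `β₁` is Bayesian, `(β₀, β₂)` stay frequentist; the two
  blocks are alternated EM-style to a fixed point: the Bayesian block is
  updated to its conditional posterior mean on the residual
  `Y − X_F β_F`, the frequentist block to conditional OLS on
  `Y − X_B β_B`. At convergence `β₁`'s standard error is its *conditional*
  posterior SD, which is strictly smaller than the all-Bayesian marginal
  SD — that is where the hybrid's extra power comes from.

σ² is plugged in once from the full OLS residuals (RSS/(n−p)) and held
fixed. Intervals are `estimate ± 1.96·se`; p-values are two-sided normal.
Genes are screened by Benjamini–Hochberg FDR (< 0.01) plus an effect-size
cut (|β̂₁| ≥ 0.585), and the selected list is tested for pathway
over-representation with the inclusive upper-tail hypergeometric p-value
and the moment z-score
`z = (r − Rn/N) / sqrt(R·(n/N)(1−n/N)·(N−R)/(N−1))`.

## Worked example

Simulate a cohort (10 control / 12 case donors, 150 cells each, 200 genes
of which 15% are differentially expressed with effect 1.0), run QC,
aggregate, screen with the hybrid method under bulk-informed priors, and
test the built-in pathways:

```python
from bfhde import (SynthConfig, generate_dataset, filter_genes, filter_cells,
                   aggregate_weighted, gene_prior_source, screen_genes,
                   run_enrichment)

data = generate_dataset(SynthConfig(n_genes=200, cells_per_donor=150,
                                    frac_de=0.15, beta1_effect=1.0, seed=7))
ds = filter_cells(filter_genes(data.cells))
pb = aggregate_weighted(ds).attach_groups(data.donors)
res = screen_genes(pb, method="hybrid", priors=gene_prior_source(data.bulk_prior))
print("selected:", len(res.selected_genes), "of", res.n_genes, "genes")
enr = run_enrichment(res.selected_genes, data.gene_sets, res.tested_genes)
print(enr.head(1).to_string(index=False))
```

prints

```
selected: 28 of 200 genes
         pathway  r  R  n   N   zscore       pvalue       qvalue
pathway_enriched 26 28 43 200 9.886094 4.290584e-19 8.581168e-18
```

— 28 genes pass the FDR and effect cuts, and the planted pathway (26 of
its 43 members among the 28 selected genes, background 200) dominates the
enrichment table. Comparing estimators on the top gene shows the hybrid's
tighter inference at an essentially unchanged point estimate:

```
     method coefficient  estimate       se        pvalue
frequentist       group  0.951345 0.064889  1.143815e-48
     hybrid       group  0.952831 0.043182 6.788227e-108
```

The same pipeline runs from the shell: `bfhde simulate --out sim` then
`bfhde run --counts sim --metadata sim/metadata.csv --phenotype
sim/phenotype.csv --bulk-prior sim/bulk_prior.csv --gene-sets
sim/gene_sets.gmt --out out` (see `bfhde --help` for stage-wise
subcommands and threshold flags).

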