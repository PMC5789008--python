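# genoclime

Population-level gene-by-environment analysis for the dopaminergic system:
does a composite index of dopamine-pathway allele frequencies predict
population mean personality traits, but only under high climatic demand?

The package is aimed at researchers working on cross-national differences in
behavioural traits who want a reproducible, tested implementation of the
gene-systems / climatic-demand interaction analysis: aggregation of
literature allele frequencies, construction of a principal-component gene
index, a thermal-demand index, and the moderated-regression machinery with
its robustness checks. Because the original data are curated from hundreds
of publications, a synthetic-data generator with the same statistical
structure is a first-class part of the package — every stage can be
exercised, end to end, without downloading anything.

## The model

**Dopamine index.** For nine polymorphisms in dopamine transporter and
receptor genes (DAT1 rs28363170 VNTR; DRD2 rs1800497, rs1079597, rs1800498,
rs6275, rs6277, rs1799732; DRD3 rs6280; DRD4 rs1800955), sample-level
frequencies of each canonical allele are aggregated per population by
sample-size weighting: `f_pj = Σ_i n_i f_ij / Σ_i n_i`. The populations ×
loci correlation matrix (pairwise complete) is repaired to the nearest
positive-semidefinite correlation matrix by eigenvalue clipping, and the
first principal component — oriented so the DAT1 9R-carrier frequency loads
positively — defines loadings λ. Population scores are

```
DA_p = Σ_j λ_j z_pj / Σ_j |λ_j|        (weights renormalised over available loci)
```

rescaled so the observed range spans 0–100. Composite reliability is the
standardised Cronbach alpha `α = k·r̄ / (1 + (k−1)·r̄)`; the agreement of
sample-level and population-level components is Tucker's congruence
`φ = Σ x_i y_i / √(Σx² · Σy²)`.

**Climatic demand.** `CD = Σ |T − 22 °C|` over four temperatures: the lowest
and highest of the coldest month and of the hottest month.

**GxE test.** With mean-centred variables, OLS of a population trait mean on
`{DA, CD, DA·CD}` (plus optional covariates and continent dummies); the
hypothesis rides on the product term, tested one-sided with an a-priori
direction (positive for approach traits such as Extraversion, negative for
Neuroticism). Reported alongside: the incremental F of the interaction
`ΔF = ΔR² / ((1−R²_full)/(n−p))`, the R² partition into main effects +
interaction, simple slopes of DA at ±1 SD of CD, a population-resampling
percentile bootstrap of the interaction, hierarchical control blocks
(wealth/parasite stress, and the competitive climate-by-wealth model), a
Mahalanobis multivariate outlier screen, and Bonferroni adjustment.

## Worked example

```python
from genoclime import (SyntheticConfig, simulate_dataset, aggregate_samples,
                       build_gene_index, sample_level_matrix, analyse_dataset)

cfg = SyntheticConfig(seed=1)                  # 40 populations, default noise
ds = simulate_dataset(cfg)
matrix = aggregate_samples(ds.sample_table)
index = build_gene_index(matrix, sample_level_matrix(ds.sample_table))
print(f"PC1 eigenvalue: {index.eigenvalues[0]:.2f} "
      f"({100 * index.variance_fractions[0]:.0f}% of variance)")
print(f"alpha = {index.alpha:.2f}, cross-level Tucker phi = {index.phi[0]:.2f}")

fit = analyse_dataset(ds, "extraversion_bfi", direction="pos",
                      bootstrap=1000, bootstrap_seed=1)
b3 = fit.terms.loc[fit.interaction_term]
print(f"interaction b3 = {b3['estimate']:.3f} (SE {b3['se']:.3f}), "
      f"one-sided p = {b3['p_one']:.2g}")
```

prints

```
PC1 eigenvalue: 8.82 (98% of variance)
alpha = 1.00, cross-level Tucker phi = 1.00
interaction b3 = 0.806 (SE 0.003), one-sided p = 1.1e-61
```

The generating interaction coefficient was β3 = 0.8: the estimation chain —
binomial sampling noise, weighted aggregation, PCA scoring, 0–100 scaling,
demand computation, moderated regression — recovers it. The simple slopes
(`fit.simple_slopes`) show the phenotypic-plasticity signature: the dopamine
slope is strongly positive one SD above mean climatic demand and reverses
below it, and the 1,000-resample bootstrap CI for b3, (0.800, 0.812),
excludes zero. With all noise switched off (`trait_noise_sd=0,
freq_noise_sd=0`) the recovery is exact to machine precision.

The same analysis is available from the shell:

```sh
genoclime simulate --seed 1 --outdir run/
genoclime aggregate --samples run/sample_table.csv --out run/matrix.csv
genoclime index --matrix run/matrix.csv --samples run/sample_table.csv --out-prefix run/dopamine
genoclime climate --in run/climate_table.csv --out run/demand.csv
genoclime gxe --data merged.csv --y extraversion_bfi --covariates wealth,parasite_stress \
              --dummies continent --bootstrap 1000 --seed 42 --direction pos --out result.json
genoclime all --config run.yaml        # the whole pipeline from a YAML config
```

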