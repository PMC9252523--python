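# adipohep

A tested pipeline for screening obesity-associated protective genes in
liver cancer cohorts, built around six analysis arms:

1. **Cohort trend comparison** — each signature gene expressed as a ratio
   to GAPDH, compared across reference-normal / adjacent-normal / tumor
   cohorts with Student's t tests (`adipohep.sex_trend.ratio_trend`).
2. **Two-gene sex inference** — 2-means clustering on
   (log2 XIST, log2 RPS4Y1) for samples without sex labels
   (`adipohep.sex_trend.infer_sex`).
3. **ssGSEA signature scoring** — per-sample weighted running-sum
   enrichment of the packaged 14-gene obesity signature, implemented from
   first principles (`adipohep.ssgsea`).
4. **Survival statistics** — univariate Cox screening (Efron ties,
   Newton-Raphson), Kaplan-Meier curves, log-rank and Gehan-Breslow
   generalized Wilcoxon tests with an exact-permutation option
   (`adipohep.survival`).
5. **Five-filter screening cascade** — obesity-score differential, female
   differential, tumor differential, protective-HR Cox screen, and
   signature-correlation filters with full per-stage provenance
   (`adipohep.cascade`).
6. **Two-sample Mendelian randomization** — harmonization, IVW and
   MR-Egger (intercept = directional-pleiotropy test), with sex-stratified
   wrappers (`adipohep.mr`).

Because the original cohorts require consortium downloads, the package
ships a first-class synthetic-cohort generator (`adipohep.simulate`) that
produces expression, survival and GWAS summary tables with planted
signals and complete ground-truth bookkeeping; every downstream stage is
tested against it.

## CLI

All commands log to stderr and write TSV/JSON data products only.

```sh
# generate a full synthetic dataset (+ ground_truth.json)
adipohep simulate --config run.yaml --outdir out/

# individual stages
adipohep sexinfer --expression out/expression.tsv --metadata out/metadata.tsv --outdir out/
adipohep trend    --expression out/expression.tsv --metadata out/metadata.tsv --outdir out/
adipohep score    --expression out/expression.tsv --metadata out/metadata.tsv --outdir out/
adipohep survival --expression out/expression.tsv --metadata out/metadata.tsv \
                  --survival out/survival.tsv --gene PROT01 --outdir out/
adipohep mr       --exposure out/gwas_exposure_all.tsv --outcome out/gwas_outcome_all.tsv --outdir out/
adipohep cascade  --expression out/expression.tsv --metadata out/metadata.tsv \
                  --survival out/survival.tsv --outdir out/

# everything, with a run manifest of per-file SHA-256 digests
adipohep run-all --config run.yaml --seed 7 --outdir out/
```

A minimal `run.yaml`:

```yaml
seed: 7
simulation:
  n_per_group: 100
  n_snps: 50
cascade:
  corr_min: 0.5
  min_correlated_signature_genes: 12
```

Re-running `run-all` with the same config and seed reproduces identical
digests for every product.

## File formats

- Expression: TSV (first column `gene_id`) or GCT 1.2, with a metadata
  sidecar TSV (`sample_id`, `cohort` in {ref_normal, adj_normal, tumor},
  `sex` in {male, female, unknown}).
- Gene sets: GMT. The 14-gene obesity signature ships as package data.
- Survival: TSV with `sample_id`, `time_days`, `event`, `sex`.
- GWAS summary statistics: TSV with `snp_id`, `effect_allele`,
  `other_allele`, `eaf`, `beta`, `se`, `pval`, `n`.

All thresholds are expression-unit-dependent; inputs are assumed
TPM-like. Writers emit canonical column order and round-trip floats
exactly.
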