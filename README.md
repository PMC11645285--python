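# pprskit

Toolkit for building and evaluating **partitioned polygenic risk scores**
(pPRS) from individual-level genotype dosages and phenotypes. Variants
associated with liver fat are split by the sign of their circulating-
triglyceride effect into a *discordant* (liver-retention) and a
*concordant* (systemic) score, whose disease associations dissociate.
Every stage is exercised end to end on synthetic cohorts with a planted
two-pathway architecture, so no restricted data are needed.

## Modules

| Module | Purpose |
| --- | --- |
| `pprskit.simdata` | synthetic cohorts: planted discordant/concordant loci, LD tags, adiposity indices, mediated effects, logistic + survival outcomes |
| `pprskit.assoc` | rank-based inverse-normal transform, vectorized per-variant linear/logistic scans, HC3 interaction tests, IVW fixed-effect meta-analysis, LD proxy lookup, Bonferroni/BH/Fisher utilities |
| `pprskit.loci` | dosage-correlation LD, greedy clumping, forward/backward stepwise conditional selection, pleiotropic locus merging |
| `pprskit.pprs` | sign-concordance partitioning, weighted-sum scoring, logistic/Cox outcome association (per-SD effects, Schoenfeld diagnostic), Wald score comparison, ΔAIC, quartile biomarker contrasts |
| `pprskit.bnmf` | variant-trait z-matrix construction and ARD Bayesian NMF soft clustering with an SNR-maximizing membership cutoff |
| `pprskit.mediation` | linear causal mediation (ACME/ADE, percentile bootstrap, optional exposure-mediator interaction), error-correlation sensitivity curve, mediation-type classification |
| `pprskit.adiposity` | lasso/ridge/elastic-net predictor ranking under nested cross-validation |
| `pprskit.io` / `pprskit.pipeline` / `pprskit.cli` | VCF (DS field) and schema-commented TSV I/O, run configuration, end-to-end orchestration, CLI |

## CLI

Every subcommand accepts `--seed`, `--config` (YAML run configuration,
see `pprskit.pipeline.RunConfig`) and `--out`:

```bash
pprskit simulate --seed 1 --out run/
pprskit scan --genotypes run/genotypes.tsv --phenotypes run/phenotypes.tsv \
    --trait PDFF --adjustment VAT --out run/pdff_vat.tsv
pprskit clump --sumstats run/pdff_vat.tsv --genotypes run/genotypes.tsv --out run/leads.tsv
pprskit partition --pdff-sumstats run/pdff.tsv --tg-sumstats run/tg.tsv --out run/partition.tsv
pprskit score --genotypes run/genotypes.tsv --partition run/partition.tsv --out run/scores.tsv
pprskit assoc --scores run/scores.tsv --phenotypes run/phenotypes.tsv \
    --outcome cardiovascular --model logistic --out run/effects.tsv
pprskit run-all --seed 1 --out run/   # whole workflow in one call
```

`run-all` chains simulate → transform → scan (per adiposity adjustment) →
clump → conditional selection → pleiotropic merge → partition → score →
outcome association → Wald/AIC comparison → bNMF clustering → mediation,
writing every stage artifact as a schema-commented TSV plus a JSON run
log; reruns with the same seed are bit-identical apart from timings.

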