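# domdev

Dominance-deviation (non-additive allelic effect) screening of
trait-associated variants, and dominance-aware polygenic risk scores, built
around the refractive-error / myopia study design:

* **Genotype handling** — hard-calling of imputed dosages (threshold 0.1),
  minor-allele orientation, MAF > 0.03 inclusion filtering, TSV/VCF I/O
  (`domdev.genotypes`).
* **Synthetic cohorts** — Hardy–Weinberg genotypes for a configurable
  variant panel (default 146 variants), a continuous refractive-error
  phenotype with additive / dominant / recessive architectures rescaled to a
  target variance explained, an age-of-onset-of-spectacle-wear (AOSW) proxy
  phenotype, and the standard covariate block (`domdev.cohort`).
* **AOSW → myopia inference** — logistic model of myopia on AOSW with dual
  ROC thresholds (myopic at ≥ 90% specificity, non-myopic at ≥ 90%
  sensitivity, unclassifiable in between) (`domdev.classify`).
* **Association models** — per-variant dominance-deviation (additive count +
  heterozygote indicator) and heterozygote-referenced genotypic models,
  logistic or linear, with covariates and Wald p-values (`domdev.assoc`).
* **Two-stage screen** — discovery filtering (nominal dominance deviation
  plus full dominant/recessive consistency), forwarding, replication with
  Bonferroni correction and the expected-by-chance count (`domdev.screen`).
* **Risk scores** — PRS #1 (additive), #2 (additive + dominance for all
  variants), #3 (dominance only for a selected subset), evaluated as
  incremental adjusted R² over an age + gender baseline with a percentile
  bootstrap CI (`domdev.prs`).
* **Accuracy-loss simulation** — the train/test experiment quantifying how
  much test-set R² a 146-variant score loses when phenotypes are generated
  under complete dominance but scored additively, across a grid of total
  variance explained (`domdev.simulation`).

## CLI

```bash
domdev simulate --out sim/ --seed 1 --n-discovery 228423 --n-replication 73577
domdev classify --pheno sim/replication_phenotypes.tsv --myopia-cut -0.75 \
    --out clf.json --apply-to sim/discovery_phenotypes.tsv
domdev assoc --model linear --pheno sim/replication_phenotypes.tsv \
    --geno sim/replication_genotypes.tsv --out assoc.tsv
domdev screen --dir sim/ --alpha 0.05 --out screen.tsv
domdev prs --dir sim/ --mode prs2 --bootstrap 2000 --out prs.tsv
domdev fig3 --reps 100 --n 75000 --grid 0.02:0.12:0.02 --seed 1 --out fig3/
domdev io-convert --geno dosages.vcf --hard-call-threshold 0.1 --min-maf 0.03 \
    --out hardcalls.tsv
domdev pipeline --out run/ --seed 1          # everything end to end
```

`domdev fig3` and `domdev simulate` accept `--panel-file` (TSV with columns
`variant_id  gene  major  minor  maf  beta  gamma  mode`) to override the
default panel, e.g. to supply published per-variant MAFs and effect sizes.

The default myopia definition is mean spherical equivalent ≤ −0.75 D; change
it with `--myopia-cut` wherever classification is involved.

## Notes on defaults

The default variant panel draws MAFs uniformly on (0.03, 0.5) and effect
magnitudes uniformly on (0.02, 0.33) with random signs; because phenotypes
are rescaled to a target variance explained, only the joint MAF/effect
spread matters. Dominant-architecture results are sensitive to the MAF
spectrum (the additive share of a completely dominant variant is
2(1−p)/(2(1−p)+p) at minor-allele frequency p); supply a panel file to
reproduce results for a specific spectrum.
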