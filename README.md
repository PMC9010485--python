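# ucigen

Exact cross-prediction engine and forward simulator for maize unilateral
cross-incompatibility (UCI) loci such as *Ga1* and *Ga2*.

A UCI locus is modeled as a pair of determinant flags per allele — a
pollen-expressed male determinant (P) acting gametophytically and a
silk-expressed female determinant (F) acting sporophytically through an
allele-dose threshold (default 2, i.e. a recessive barrier). From that
single rule the package derives, by exact enumeration rather than
sampling:

* gamete and offspring distributions under recombination and pollen
  selection, including barren ears, mixed and sequential pollen pools,
  kernel-colour and transgene readouts (`ucigen.cross_engine`);
* an executable catalog of the classical segregation, transgenic-validation
  and pyramiding experiments, each reduced to a predicted class ratio, with
  architecture-comparison runs (sporophytic-male, dose-threshold-1,
  gametophytic-female variants) to show which designs discriminate which
  hypotheses (`ucigen.designs`);
* goodness-of-fit (Pearson chi-square), exact multinomial tests, exact
  power, and ratio model ranking for observed count data
  (`ucigen.segstats`);
* simulation and expectation calculus for recombinant fine-mapping screens
  — gametic-selection homogeneous populations, genotype+phenotype screens,
  interval localization from recombinant constraint intersection, and
  marker-assisted backcross programs (`ucigen.mapping_sim`);
* seeded synthetic datasets (count tables, marker tables, per-ear kernel
  counts) with configurable misclassification, contamination and
  genotyping-error rates (`ucigen.synthetic_data`).

## CLI

The console script `ucigen` exposes the engine:

```sh
ucigen predict D7                       # exact prediction for a catalog design
ucigen predict D7 --override Ga2.female_dose_threshold=1
ucigen gof --counts counts.tsv --ratio 7:1 --ratio 8:1
ucigen power --null 8:1 --true 7:1 -n 188
ucigen --seed 3 simulate counts D7 -n 188
ucigen --seed 3 simulate markers male_screen -n 16544
ucigen --seed 1 mapsim --screen male -n 16544
ucigen reproduce-paper --out report.tsv # predictions vs bundled observations
```

Tables are strict TSV with `#`-comment headers recording the seed and
config hash; exit codes are 0 (success), 2 (usage error), 3 (data-format
error). A YAML config (`--config`) can override the seed, noise rates,
marker-panel rate and locus architectures; unknown keys are rejected.

## Notes on the model

* The female barrier is an allele-dose threshold, not a hardcoded
  homozygosity test: the same rule reproduces the recessive heterozygote,
  the inert hemizygous transgene, and the active homozygous transgene.
* Transgene loci are unlinked UCI loci carrying a `specificity` pointer to
  the barrier system they belong to, so an F transgene erects a barrier
  that native M-haplotype pollen passes.
* Seed set uses a pollen-excess saturation model (any compatible fraction
  gives a full ear), matching the binary full-vs-<5-seeds field phenotype.
* The model's exact enumeration for the female BC1F2 test gives 7:1
  (no-seed probability 1/8); the reported 8:1 claim is carried alongside
  and both are testable against observed counts — at n=188 the exact test
  has only ~0.10 power to separate them.
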