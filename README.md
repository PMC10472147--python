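# sibstep

Pedigree BLUP (PBLUP) and single-step genomic BLUP (ssGBLUP) for
embryo-transfer-style full-sib family designs, with a synthetic data
generator.

Full sibs without phenotypes are indistinguishable to a pedigree-only
evaluation: the numerator relationship matrix assigns every pair of them the
same expected relationship (0.5 for non-inbred parents), so their estimated
breeding values (EBVs) collapse to one value per family. Adding genotypes
through the single-step H matrix recovers each animal's realized (Mendelian
sampling) deviation, giving individual genomic EBVs (GEBVs) with higher
accuracy. This package implements both evaluations end to end and a
simulator that reproduces the contrast at desk scale.

## What is inside

- `sibstep.pedigree` — pedigree reading/validation/renumbering, the tabular
  numerator relationship matrix `A`, its sparse inverse (Henderson's rules
  with Meuwissen–Luo inbreeding), the genotyped sub-block `A22`, and
  full-sib / half-sib / low-related (RT3/RT2/RT1) pair classification with
  per-stratum relationship summaries.
- `sibstep.genotype` — dosage I/O (simple TSV and PLINK `.raw`), SNP QC
  (MAF < 0.01, missingness ≥ 0.10, exact HWE test p < 1e-6, mean
  imputation), the VanRaden genomic relationship matrix `G`, and single-step
  `H⁻¹ = A⁻¹ + [0 0; 0 (G*)⁻¹ − A22⁻¹]` with configurable G blending.
- `sibstep.mixedmodel` — animal-model mixed-model equations under either
  `A⁻¹` or `H⁻¹`, direct solving, prediction error variance from the inverse
  coefficient matrix, accuracy (reliability-form by default, sqrt mode
  available), heritability, slaughter-age phenotype filters, and EM-REML
  variance-component estimation.
- `sibstep.simulate` — seeded generator: reference tier of phenotyped
  half-sib families plus genotyped, phenotype-free full-sib test families;
  Mendelian gene dropping from HWE founders; genic or pedigree-recursion
  true breeding values; retained truth for recovery tests.
- `sibstep.compare` / `sibstep.cli` — one-command pipeline running both
  methods on the same inputs and reporting per-method components/h²/accuracy,
  per-family EBV vs GEBV means and SDs, and relationship distributions per
  stratum.

## CLI

```sh
# generate a synthetic dataset
sibstep simulate --seed 1 --outdir runs/sim

# full two-method comparison on simulated data
sibstep compare --simulate --seed 1 --outdir runs/cmp --alpha-from fixed
sibstep report --run-dir runs/cmp

# single-method evaluations from files
sibstep pblup --pedigree ped.csv --phenotypes phen.csv --reml --out ebv.tsv
sibstep ssgblup --pedigree ped.csv --phenotypes phen.csv \
    --genotypes geno.tsv --sigma-a2 40 --sigma-e2 60 --out gebv.tsv
```

`compare` writes `report.json` (components, heritabilities, mean accuracies,
per-family EBV/GEBV contrast, RT1/RT2/RT3 relationship summaries, full run
manifest), per-method result TSVs, the QC report, and the simulated inputs.

## File formats

- Pedigree: headered CSV `animal,sire,dam`, `0` or empty = unknown parent.
- Phenotypes: headered CSV `animal,<trait...>,birth_year,birth_month,
  slaughter_age_months,slaughter_place`.
- Genotypes: TSV `animal_id` + one 0/1/2/NA column per SNP, or PLINK `.raw`.
- Relationship matrices export as 3-column sparse text (lower triangle).
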