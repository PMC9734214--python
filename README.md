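# genebankgp

Genomic prediction for structured genebank panels of inbred lines:
genotype QC, population-structure analysis, additive/epistatic kernels,
REML mixed models and a repeated fivefold cross-validation protocol,
together with a synthetic-data generator for admixed inbred panels.

## What it implements

- **`genotype_qc`** — TSV/VCF genotype I/O and a three-step marker QC
  pipeline: filter (missingness > 10%, < 10 homozygotes per allele,
  heterozygosity > 1%), impute missing calls to the dominant allele's
  homozygous dosage, re-filter markers with MAF < 1%.
- **`popstructure`** — pairwise Rogers' distances, principal coordinate
  analysis, admixture estimation (masked alternating least squares with a
  row-simplex ancestry matrix, scored by binomial cross-entropy on held-out
  entries, best-of-repeats), cross-entropy model choice over a range of k,
  phenotype Euclidean distances on complete cases, and between-subpopulation
  distance contrasts.
- **`kernels`** — VanRaden (method 1) additive relationship matrix G, the
  Hadamard-square epistatic kernel H = G∘G, and the design matrices of the
  ridge-regression family: a general centered dosage matrix plus hard-label
  masked or admixture-weighted per-subpopulation copies.
- **`mixed_model`** — REML + BLUP for the full model zoo: single-kernel
  models via an eigendecomposition fast path (additive-kernel BLUP and its
  fixed-marker extension), multi-kernel models via fixed-point warm start
  plus average-information REML (epistatic extension; general +
  subpopulation-specific ridge models solved in kernel space with
  marker-effect back-solving). All fitters accept fixed variance
  components for oracle checking.
- **`gwas`** — P3D mixed-linear-model scan, effective-test-count
  multiple-testing correction from the marker correlation spectrum
  (blockwise eigendecomposition), per-marker explained variance, and the
  four fixed-marker selection strategies (top association, top variance,
  cumulative-10% prefix, all significant) with feasibility reporting.
- **`evaluation`** — repeated fivefold CV with combined-then-correlate
  prediction abilities, optional stratification, per-subpopulation scopes,
  and the contrasting-subpopulation scenario with optional size
  equalization.
- **`synthetic_data`** — admixed inbred panel simulator (recentered
  Balding–Nichols allele-frequency profiles, Dirichlet admixture with a
  dominant component, optional outgroup, missing/heterozygous calls) and a
  trait simulator (general additive + admixture-weighted
  subpopulation-specific + additive-by-additive epistatic + major-QTL
  effects at a target heritability, incomplete phenotyping).
- **`cli`** — `genebankgp` command with subcommands `simulate`, `qc`,
  `structure`, `gwas`, `crossval`, `predict` and `full-study` (end-to-end:
  QC → structure → model comparison → best-model catalogue of predicted
  phenotypes for unphenotyped samples).

## CLI quick start

```bash
# simulate a structured panel with one trait
genebankgp simulate --n-samples 300 --n-markers 800 --k-pops 3 \
    --divergence 0.3 --concentration 0.2 --seed 1 --out data/

# QC, population structure, model comparison
genebankgp qc --genotypes data/genotypes.tsv --out qc/
genebankgp structure --genotypes qc/genotypes_qc.tsv --k-min 1 --k-max 6 --out structure/
genebankgp crossval --genotypes qc/genotypes_qc.tsv --blues data/blues.csv \
    --trait trait --models G-BLUP,EG-BLUP,GSA-RRBLUP_adm --k 3 --out cv/

# full pipeline, ending in a catalogue of predicted phenotypes
genebankgp full-study --genotypes data/genotypes.tsv --blues data/blues.csv \
    --models G-BLUP,EG-BLUP --out study/
```

Model names: `G-BLUP`, `EG-BLUP`, `RR-BLUP`, `W-BLUP_S1` … `W-BLUP_S4`,
`GSA-RRBLUP_k<k>`, `GSA-RRBLUP_adm_k<k>`.

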