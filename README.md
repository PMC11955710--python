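# poolpop

Pooled-GBS germplasm characterization in Python: from per-replicate pooled
allele counts to population structure, diversity statistics, relationship
matrices, REML variance components with narrow-sense heritability, and
RDA-based landscape genomics — together with a seeded synthetic-data
generator that emulates the statistical structure the pipeline assumes
(drift-structured clusters, finite bulks with technical replicates,
cluster-linked bioclimatic variables with planted adaptive loci, and
mixed-model phenotypes).

## Modules

| Module | Purpose |
| --- | --- |
| `poolpop.simulate` | Seeded generators: Balding–Nichols cluster frequencies, pooled read counts, bioclim + adaptive loci, phenotypes, pedigree and gene-model fixtures; VCF/GFF3 writers |
| `poolpop.poolfreq` | AAF = Alt/(Alt+Ref), replicate merging, three-rule SNP filtering, per-locus mean imputation; VCF/TSV ingestion |
| `poolpop.diversity` | Modified Rogers Distance, expected heterozygosity, pairwise Nei-type FST, gene flow Nm = (1−FST)/(4·FST) with grade labels, hierarchical AMOVA with permutation tests |
| `poolpop.structure` | PCA of frequencies, a-score PC selection, k-means with BIC model choice, DAPC membership probabilities |
| `poolpop.kinship` | VanRaden genomic relationship matrix from pooled dosages; pedigree A-matrix (tabular method) and inbreeding coefficients |
| `poolpop.quantgen` | AI-REML variance components with a genomic covariance, boundary-mixture LRTs, GBLUPs, narrow-sense heritability, trait-GBLUP PCA |
| `poolpop.landscape` | Collinearity pruning (r ≥ 0.8), redundancy analysis, 3-SD candidate-SNP detection, predictor assignment with BH FDR, cluster chi-square tests, nearest-gene annotation within 3 kb |
| `poolpop.cli` | `poolpop` command-line pipeline with a JSON run manifest |

## Command-line usage

```bash
poolpop --seed 1 --out-dir run1 simulate   # synthetic VCF, phenotypes, bioclim, GFF3
poolpop --seed 1 --out-dir run1 freqs      # merge, filter, impute
poolpop --seed 1 --out-dir run1 diversity  # MRD, He, FST/Nm, AMOVA
poolpop --seed 1 --out-dir run1 structure  # PCA, BIC, DAPC memberships
poolpop --seed 1 --out-dir run1 kinship    # G-matrix, A-matrix, inbreeding
poolpop --seed 1 --out-dir run1 quantgen   # REML components, h2, GBLUPs
poolpop --seed 1 --out-dir run1 landscape  # pruning, RDA, candidates, genes
poolpop --seed 1 --out-dir run1 all        # everything in order
```

A YAML config (`--config`) overrides any threshold (filter bounds,
collinearity r, SD multiplier, permutation counts, trait variance
components, …). Every stage appends record counts and content digests to
`<out-dir>/manifest.json`; runs are reproducible from the global seed.

Real data drop in at the same interfaces: a VCF 4.2 with per-sample AD
fields (`poolpop freqs --vcf calls.vcf`, samples named
`<population>_rep<k>`), plot-level phenotype CSV, population × Bio1–Bio19
CSV, 3-column pedigree CSV, and GFF3 gene models.

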