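# pathperm

Pathway analysis of GWAS summary statistics with **circular genomic
permutation**.

## The problem

Single-marker genome-wide association studies leave most truly associated
variants below the genome-wide significance threshold. Gene-set (pathway)
analysis recovers some of that signal by asking whether the genes of a
pathway are jointly enriched for association. The catch is the null
distribution: SNP association P values are correlated along the genome
through linkage disequilibrium (LD), and functionally related genes cluster
physically, so naive permutation schemes that shuffle P values freely
produce badly calibrated pathway P values.

`pathperm` implements a permutation scheme that needs only summary
statistics (no genotypes): all SNPs are placed on a circular genome ordered
by chromosome and position, and the entire vector of association P values
is **rotated** by a random offset. Every SNP keeps its neighbours — LD
structure and gene co-location survive into the null — while the assignment
of P values to loci is randomised.

## The method

For each trait:

1. **Annotation.** SNP *i* is assigned to gene *g* when it lies within
   `window_bp` of the gene's transcription span (0 bp or 20 kb are typical).
   A SNP may hit several genes; unannotated SNPs stay on the circle.
2. **Gene scores.** A gene with SNP P values *P₁…P\_K* gets the Fisher
   combination score *Z\_F = −2 Σᵢ ln Pᵢ*, referred to χ²(2K); for K = 1 the
   gene P value is the SNP P value.
3. **Pathway test.** With *N* scored genes of which *S* have gene P ≤ α
   (default α = 0.05), a pathway covering *m* genes with *K* significant
   gets the hypergeometric tail P(X ≥ K).
4. **Calibration.** The P-value vector is rotated by a uniform random
   offset; gene scores, *S* and every pathway statistic are recomputed —
   10,000 times by default. The empirical P value is the rank of the
   observed statistic, (r+1)/(n\_perm+1); the empirical 5% significance
   threshold is the 5th percentile of the permuted statistics.

Alternative null schemes (`circular-per-chrom`, `snp-random`,
`gene-random`) are provided for comparison; gene-level resampling
reproduces the theoretical hypergeometric P values almost exactly and
serves as an internal consistency check.

## Worked example

Everything below is synthetic — the package ships a generator whose AR(1)
latent scores mimic LD and whose pathways can carry planted effects:

```python
from pathperm import PathwayEnrichment, SimulationConfig, simulate_genome

cfg = SimulationConfig(n_snps=5000, n_chromosomes=5, n_genes=500, ld_rho=0.9,
                       n_pathways=40, pathway_size_range=(8, 30),
                       gene_clustering=0.8, planted_pathways=((4, 1.5),),
                       n_traits=1, seed=11)
gwas, genes, sets = simulate_genome(cfg)

model = PathwayEnrichment(gwas, genes, sets, window_bp=0, alpha_gene=0.05)
res = model.fit(scheme="circular", n_perm=2000, seed=3)
print(res.summary(top=5))
```

```
Pathway enrichment (permutation-calibrated hypergeometric test)
==================================================================
scheme: circular    permutations: 2000    seed: 3
annotation window: 0 bp    alpha_gene: 0.05    level: 0.05
tests: 40    expected by chance: 2
theoretically significant (P <= 0.05): 6
empirically significant  (P <= 0.05): 4    (overlap 4)

top 5 tests by empirical P:
pathway_id   trait  genes_in_pathway  significant_genes  theoretical_p  empirical_p  empirical_threshold
     P0005 trait_1                29                 24      5.259e-16    0.0004998              0.01591
     P0036 trait_1                 8                  5       0.004181     0.005997               0.0316
     P0002 trait_1                11                  6       0.004053      0.01099              0.03952
     P0014 trait_1                12                  5        0.03394      0.04998              0.03562
     P0029 trait_1                18                  7        0.01821      0.05047              0.01821
```

The planted pathway (`P0005`) is recovered with an empirical P of 5×10⁻⁴.
Note the calibration at work: six pathways clear the nominal 0.05 cutoff on
the theoretical hypergeometric P value, but only four survive the circular
permutation null, and most empirical 5% thresholds sit well below 0.05 —
under strong LD the theoretical test is too liberal.

The same analysis from the shell:

```bash
pathperm simulate sim.yaml --out-dir fixture --seed 11
pathperm run --gwas fixture/gwas.tsv --genes fixture/genes.tsv \
             --gmt fixture/pathways.gmt --scheme circular \
             --n-perm 10000 --seed 3 --out-dir results
pathperm summarize results/pathway_results.tsv
```

Input formats: GWAS summary TSV (`snp`, `chr`, `pos`, one column per
trait), gene TSV (`gene_id`, `symbol`, `chr`, `tx_start`, `tx_end`,
1-based inclusive), and standard GMT gene sets.

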