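# Methods

## Model and procedure

`pathperm` tests whether predefined gene sets (pathways) are enriched for
trait-associated genes, using only GWAS summary statistics: one association
P value per SNP per trait.

**Gene scores.** Each gene's K annotated SNP P values are combined with
Fisher's statistic Z_F = −2 Σ_{i=1..K} ln P_i, referred to the upper tail
of χ² with 2K degrees of freedom (implemented as the regularised upper
incomplete gamma function Q(K, Z_F/2)). Natural logarithms are used
throughout; for K = 1 the transform is the identity on (0, 1], which is the
regression test for the choice of reference distribution. No within-gene LD
correction (e.g. an effective number of tests) is applied: within-gene
correlation is deliberately left intact so the circular permutation null
absorbs it. Scoring by the best SNP per gene is not offered — it favours
long genes.

**Pathway statistic.** With a universe of N scored genes, S of them
significant (gene P ≤ alpha_gene, boundary inclusive), a pathway covering m
universe genes with K significant members is scored by the hypergeometric
tail P(X ≥ K) (population N, S successes, m draws). The inclusive tail is
the default; a strict-tail variant P(X > K) is available via `tail="gt"`
and is anti-conservative relative to the default by exactly the point mass
at K. Because the same statistic is used for observed and permuted data,
empirical calibration is valid under either convention. The universe
defaults to every gene with at least one annotated SNP;
`universe="pathway-genes"` restricts it to pathway members.

**Circular null.** SNPs are ordered by (chromosome, position), ties broken
by SNP id, chromosomes concatenated in a configurable order (default 1..22,
X) and closed into a circle. Per permutation one offset is drawn uniformly
from {1, …, n−1} and the entire P-value vector rotates by it — annotated
and unannotated SNPs alike — after which gene scores, S, and every
pathway's statistic are recomputed; one offset serves all pathways so the
joint structure of the permuted statistics is preserved. The identity
rotation is excluded by default so every permutation is a genuine
rearrangement; this matters only for small genomes (probability 1/n) and
`allow_identity=True` restores the wider support. A per-chromosome variant
(`circular-per-chrom`) draws an independent offset per chromosome block.

**Comparison nulls.** `snp-random` replaces the rotation with a full random
reassignment of P values to SNPs (each gene of K SNPs then receives K
values drawn without replacement from the pool), destroying positional
correlation. `gene-random` computes gene P values once from the observed
data and resamples m genes per pathway without replacement from the
universe, holding S and N fixed; this re-enacts the hypergeometric model
and its empirical P values track the theoretical ones at rank correlation
≈ 1 — an internal consistency check, not a calibration method.

**Empirical quantities.** The empirical P value is (r + 1) / (n_perm + 1),
where r counts permuted statistics ≤ the observed one; ties count towards
r (conservative), the estimator never returns 0, and it is exact under
exchangeability. The empirical significance threshold at level q is the
⌈q·n_perm⌉-th smallest permuted statistic; an observed theoretical P at or
below it is empirically significant at q. Counting significance via
empirical_p ≤ q agrees with the threshold rule up to the +1 finite-sample
correction of the estimator.

## Randomness and reproducibility

All randomness flows through `numpy.random.default_rng`. In a multi-trait
fit each trait receives an independent child stream spawned from the master
seed (`SeedSequence.generate_state`), so adding a trait never perturbs
another trait's null; `shared_offsets=True` instead reuses one stream
across traits, preserving the cross-trait correlation of null statistics.
Identical inputs and seed give bit-identical results across runs and
schemes.

## Performance

Gene → genome-rank index lists and pathway → gene lists are flattened once;
each permutation is evaluated by modular index arithmetic, a segmented sum
(`np.add.reduceat`) for the Fisher scores, a vectorised incomplete-gamma
call, and one vectorised hypergeometric tail per pathway vector. No shuffled
table is ever materialised. At 2×10⁴ SNPs, 2×10³ genes and 225 pathways a
rotation costs ≈2.5 ms on one core (≈25 s for 10⁴ permutations per trait);
cost scales roughly linearly in annotated SNP-gene links plus pathways.

## The synthetic-data generator

The generator produces the three inputs with the two structural features
the circular null exists to respect:

* **LD-like correlation** — per trait a latent score follows a stationary
  unit-variance AR(1) process with lag-1 correlation `ld_rho` along the
  genome order; the SNP P value is the upper-tail standard-normal
  probability of the score. `ld_rho = 0` gives i.i.d. uniform P values;
  0.8–0.95 mimics dense-array LD. The process runs across chromosome
  boundaries, a deliberate simplification (a rotation also crosses them).
* **Gene and pathway geometry** — genes cover contiguous SNP blocks (sizes
  1 + Poisson(`snps_per_gene_mean` − 1), placed with multinomial gaps of
  unannotated SNPs), so the window-0 annotation recovers the construction
  exactly; `gene_clustering` sets the fraction of each pathway's genes laid
  down as a contiguous genomic block, the rest scattered.
* **Effects** — a planted pathway adds `effect_strength` to the latent
  scores of all SNPs of its member genes (on every trait), dragging their
  P values towards 0; effects of overlapping planted pathways add.

Chromosome SNP counts are equal by default (`chromosome_lengths`
overrides). Inter-SNP spacings are uniform on 1–5 kb. What the generator
does **not** model: genotypes, allele frequencies, haplotype block
boundaries, non-stationary LD, overlapping genes, and realistic pathway
overlap structure. Passing tests therefore demonstrate the statistical
machinery — calibration under autocorrelation and clustering, power against
mean shifts — not performance on any particular real cohort.

Default sizes (10⁴ SNPs, 10³ genes, 50 pathways) are a deliberate
mid-sized-study scale; tests and the acceptance script use smaller genomes
(450–6000 SNPs) chosen so each statistical check has the test size and
replicate count its oracle requires.

## Numerical choices and edge cases

* P values must lie in (0, 1]; a P of exactly 0 is rejected at input
  (Fisher takes logs) unless `clamp_pmin` replaces it with 1e-300.
* Window boundaries are inclusive on both sides; coordinates are 1-based
  inclusive.
* Chromosome labels outside the configured order are an error, never
  silently dropped — the circular order must be total.
* Genome-order ties at identical (chromosome, position) are broken by
  lexicographic SNP id, making the rotation deterministic.
* Pathways with no gene in the universe are skipped with a logged notice;
  a universe gene without a score is an error.
* The hypergeometric tail is clipped to [0, 1] to absorb last-ulp noise in
  the survival function; exactness to 1e-12 against rational enumeration is
  tested for all populations N ≤ 25.
* `empirical_threshold` requires 0 < level < 1; with a constant permuted
  distribution the threshold equals that constant and the empirical P is 1.

## Calibration subtleties

The hypergeometric statistic is discrete. With small pathways and a strict
gene cutoff its null support is coarse (an atom at P = 1 when K = 0), and
the tie-inclusive rank estimator is then conservative: empirical P values
are stochastically larger than uniform, though rejection at the 5% level
stays at or below nominal. The uniformity property test therefore uses a
configuration with rich support (pathway of 40 singleton genes, gene cutoff
0.3); the end-to-end calibration check uses the default cutoff and verifies
the rejection *rate* rather than full uniformity.

## Known limitations

* Rotation preserves adjacency but assumes the P-value field is
  (circularly) stationary; a single locus with extreme signal makes the
  null conservative for pathways near it.
* The method inherits Fisher's sensitivity to many weakly associated SNPs
  in long genes (a long gene full of null SNPs dilutes a true signal).
* No multiple-testing correction is applied across the pathway × trait
  grid; reported significance is per test, with the expected-by-chance
  count surfaced in every summary.
* Positions are taken as given; no liftover between genome builds is
  performed.
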