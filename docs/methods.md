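# Methods

`corepanel` implements a core-SNP screening and validation workflow for
distinguishing crop/cultivar germplasms from reduced-representation
(GBS-style) genotype data. This note records the models and procedures, the
parameters that matter, the numerical choices, and what the bundled
simulator does and does not emulate.

## Data model

Genotypes are diploid biallelic codes per sample × locus call: 0 (hom-ref),
1 (het), 2 (hom-alt), with a distinguished missing sentinel that is never
conflated with code 0. Coding is phase-agnostic; a half-missing VCF call
(`./1`) is treated as missing because a single observed allele does not
determine a diploid genotype. Multi-allelic records are ingested and
flagged, not rejected at parse time, so the biallelic filter is the single
authority that removes and counts them; any non-ACGT allele (spanning
deletions, symbolic alleles, indels) disqualifies a locus from biallelic
status. Positions are 1-based (VCF convention); density windows are
half-open.

## The screening cascade

Six stages, each with a literal boundary convention, producing an exact
per-stage audit trail (`FilterReport`):

1. **Depth / biallelic.** Calls with depth ≤ 4 are masked missing
   (retention requires depth strictly > 4); non-biallelic loci are removed.
   The survivors are the "total SNPs" every later comparison refers to.
2. **Cultivar consensus.** Within each cultivar, the modal genotype among
   non-missing member calls becomes the cultivar's genotype when its
   identity rate (modal / non-missing) is ≥ 0.70, otherwise the cultivar is
   missing at that locus. Because the threshold exceeds 0.5, a qualifying
   mode is unique, so the rule is invariant to sample order and tie-break
   policy.
3. **Polymorphism and Hardy–Weinberg.** Loci whose non-missing consensus
   calls are all identical are removed (all-missing counts as
   non-polymorphic; missing calls are ignored in the comparison). The HWE
   exact test (Levene/Haldane conditional distribution; two-sided p sums
   all heterozygote configurations no more probable than the observed one)
   removes loci with p < 1e-5. The test runs on the **pooled sample-level**
   genotype counts: with only 4 consensus genotypes the exact p-value can
   never reach 1e-5, so a consensus-level HWE filter would be vacuous — a
   `hwe_level` switch exposes both levels, defaulting to samples.
4. **Missingness / MAF.** Computed on the **consensus** matrix (2 alleles
   per cultivar, 8 total at 4 cultivars): loci with missingness > 0.30 or
   MAF < 0.01 are removed. At 4 cultivars the attainable non-zero consensus
   MAFs are multiples of 0.125, which is why the workflow's reported core
   MAF ranges are coarse.
5. **PIC.** Botstein polymorphic information content from consensus allele
   frequencies, `PIC = 1 − (p² + q²) − 2p²q²`; loci with PIC < 0.1 removed.
   Note that at 4 cultivars any polymorphic locus already has consensus
   MAF ≥ 0.125 and hence PIC ≥ 0.195, so with default thresholds this stage
   only bites when cultivars number more than ~6 or the threshold is raised.
6. **LD pruning.** PLINK-style sliding window on sample-level dosages
   (window 50 SNPs, step 10, per chromosome in position order). Pairs are
   scanned in order; when a retained pair has squared Pearson dosage
   correlation > 0.99 (pairwise-complete samples; undefined correlations
   treated as 0), the lower-MAF member is removed, ties dropping the later
   locus — matching PLINK 1.9's greedy behaviour. EM haplotype r² is not
   implemented; genotype-count r² is what `--indep-pairwise` uses for
   pruning.

Missing calls never count as match or mismatch anywhere; denominators
shrink accordingly.

## Summary statistics

For alt-allele frequency p among non-missing calls: MAF = min(p, 1−p);
Ho = fraction of het calls; He ("genetic diversity") = 2pq; Pi = unbiased
per-site diversity 2pq·n/(n−1) over n non-missing alleles (can exceed 0.5
slightly, which is why published total-panel diversity maxima above 0.5 are
consistent with the unbiased estimator); PIC as above. Core-panel summaries
are computed on the consensus matrix and total-panel summaries on
sample-level genotypes, mirroring where each filter operates; both
statistics (He and Pi) are always reported so no guess is needed about
which one a given figure plots. Tables round to 3 decimals, half-up.
Density tables count loci per 500 kb window (window = step by default,
tiling each chromosome).

## Similarity validation

Pair similarity = consistent genotype codes / commonly observed loci
(het matches only het, read literally). The validation regresses core-panel
similarity on total-SNP similarity over the n(n−1)/2 = 780 unordered pairs
(self-pairs excluded — including the diagonal would inflate r), reporting
OLS slope/intercept and Pearson r with the two-sided t-transform p-value.
On the default fixture the cascade-selected panel achieves r ≈ 0.996.

## Structure analyses

* **Fingerprints**: per sample, one character per locus — ref base, IUPAC
  ambiguity code, alt base, or `-` for missing — concatenated head to tail;
  the encoding is a bijection on non-missing calls.
* **p-distance / NJ**: mismatches over compared positions (missing
  excluded), identically the complement of the similarity statistic.
  Neighbor joining is delegated to scikit-bio's Saitou–Nei implementation;
  on additive matrices it is exact. Negative branch-length estimates are
  clamped to zero (scikit-bio's behaviour; the deficit is not transferred
  to the sibling edge). Bootstrap resamples loci (columns) with
  replacement; supports are fractions of replicates containing each
  internal bipartition of the full-data tree, attached to bipartitions,
  not node labels.
* **PCA**: GRM from standardized dosages `(x − 2p)/√(2p(1−p))`, missing
  calls mean-imputed via centering (the GCTA-equivalent construction);
  coordinates are eigenvectors scaled by √eigenvalue, variance fractions
  over the positive eigenvalue mass.
* **Admixture**: the K-population binomial mixture
  `g_ij ~ Binomial(2, Σ_k q_ik f_kj)` maximized by EM (FRAPPE-style
  multiplicative updates) with random restarts (default 8), tolerance 1e-6
  relative log-likelihood change, max 2,000 iterations; frequencies are
  clipped to [1e-6, 1−1e-6] for stability. EM replaces the
  block-relaxation/quasi-Newton optimizer of dedicated admixture software:
  the likelihood is the same and the scale here (40 samples × ≤20k loci)
  does not need the faster optimizer — a documented fidelity trade-off.
  The log-likelihood is monotone along every EM path (asserted in tests).
* **K selection**: non-missing genotype entries are partitioned into folds
  (default 5); per fold the entries are masked, the model refitted, and
  held-out entries scored by RMSE of `g − 2·QF`; K* is the argmin of the
  mean CV error, ties resolved toward smaller K. Deviance-based CV error is
  a possible alternative switch; RMSE is the implemented default.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: 4 cultivar
populations × 10 diploid seedlings, 31 chromosomes, mean per-call depth
11.6×. Ancestral minor-allele frequencies are Uniform(0.05, 0.5) (assigned
to ref or alt at random), so the MAF < 0.01 filter removes only
drift-created rare variants; population frequencies follow the
Balding–Nichols Beta with drift parameter Fst = 0.2 by default (shapes
`p(1−F)/F`, `(1−p)(1−F)/F`); genotypes are Binomial(2, freq) — HWE within
population; depth is Poisson(11.6); a call is missing completely at random
(rate 0.05) or when its depth is ≤ 4, so the depth filter has real work.
Balding–Nichols was chosen over a coalescent simulation because the
analysis only needs exchangeable biallelic SNPs with tunable
differentiation; there is no LD model by default. Two opt-in knobs create
regimes the baseline lacks: `dup_fraction` block-copies loci to adjacent
positions with small flip noise (high-r² pairs for exercising LD pruning),
and `admixture_noise` mixes a small off-cultivar ancestry fraction into
each sample so within-cultivar identity drops below 100% and the 70%
consensus rule is non-trivial. Both default to 0 so that the baseline
fixture is exactly Balding–Nichols + HWE, which the calibration tests rely
on.

The default locus count is 40,000. That is far below a real GBS call set
(hundreds of thousands of SNPs) but large enough that ~3,000 loci survive
through the PIC stage, comfortably supporting the K-selection analysis on
2,000 of them while keeping a full pipeline run in minutes on one CPU.

What passing tests on this generator show — and what they do not: the
fixture has no linkage disequilibrium (beyond the opt-in duplicated
blocks), no genotyping error conditional on a confident call, no
depth–allele-balance coupling, MCAR rather than informative missingness,
and equal drift in all four populations. Results on real GBS data can
differ in all of those directions; the tests demonstrate correctness of
the algorithms and recoverability under the stated model, not robustness
to artifacts the model excludes.

### Calibration of the exact test

Exact conditional tests on discrete genotype counts are conservative:
raw p-values are stochastically larger than uniform, so a
Kolmogorov–Smirnov check of raw p-values against Uniform(0,1) fails even
when everything is correct. Calibration therefore uses randomized (fuzzy)
p-values `p_less + U·p_equal`, which are exactly uniform if and only if
heterozygote counts really follow the Levene/Haldane distribution — a
joint check of the simulator's within-population HWE and the test's null
distribution. The screening filter itself uses the standard conservative
p-value, as screening tools do.

## Numerical and degenerate-input conventions

* HWE with zero observations returns p = 1 (no evidence); probability ties
  in the exact tail are grouped with a 1e-9 relative epsilon so symmetric
  configurations are included exactly as rational-arithmetic enumeration
  does (agreement to 1e-12 for all tables with n ≤ 25).
* A locus subset for similarity must be non-empty; a pair with no common
  loci has undefined (NaN) similarity and is dropped from the correlation;
  fewer than 3 defined pairs or zero variance is an error.
* An empty surviving panel is a valid cascade outcome (warning logged,
  complete report retained).
* LD windows with fewer than 2 loci keep everything; correlations over
  fewer than 2 complete pairs are treated as 0 (not prunable).
* The pipeline fans a single global seed out to per-stage seeds (CRC-32 of
  the stage name), so stages are independently reproducible; simulator
  outputs are byte-identical across runs with the same config and seed.

## Known limitations

* Consensus-level filters assume few cultivars; with many cultivars the
  consensus MAF grid becomes fine and the PIC stage regains bite.
* The admixture EM can need many iterations near degenerate optima at
  K > true K; restarts mitigate but do not guarantee the global optimum.
* NJ negative-branch clamping loses the (tiny) deficit rather than
  transferring it to the sibling edge.
* The VCF writer emits only GT:DP; other FORMAT fields present on input
  are not round-tripped.
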