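# Methods

This note documents the models, defaults and numerical choices behind
msatpop, and what the synthetic-data tests do and do not demonstrate
about real data.

## Genotype calling from amplicon reads

**Read QC.** A read is kept iff its length is ≥ `min_len` (default 75 bp)
and its *mean* Phred score is ≥ `min_phred` (default 30).  Mean-quality
filtering follows the common usage of whole-read quality tools; no
per-base trimming is performed.  Both thresholds are configurable.

**Locus assignment and tract measurement.** Instead of a mapping +
realignment + repeat-genotyper chain, reads are assigned and measured in
one step by exact flank anchoring: the last `flank_k` (default 8) bases
of the left flank and the first `flank_k` bases of the right flank must
occur, in order, in the read or its reverse complement, and the enclosed
segment must be a non-empty whole-number repetition of the locus motif.
This is deterministic and dependency-free, with the same intent as the
mapping chain it replaces.  Consequences to be aware of:

* a substitution error inside the tract or within an anchor discards the
  read (tallied in `n_discarded`), it never fabricates an allele;
* interrupted (non-whole-motif) repeats are not called — by design;
* SNPs in the flanks of real samples would also discard reads; real-data
  use may warrant a larger `flank_k` tolerance layer, which is out of
  scope here.

**Calling rule.** Per individual × locus, with per-allele read counts:
depth < `min_depth` (10) → NA; top-allele fraction > `major_threshold`
(0.80, strict) → homozygote; else second-allele fraction ≥
`minor_threshold` (0.20, inclusive) → heterozygote of the top two; else
NA.  Count ties rank the shorter tract first (a deterministic choice;
the rule's sources are silent on ties).  At depth 10 the 20% floor means
a minor allele needs ≥ 2 supporting reads; a single stray read yields a
homozygote call (fraction 0.9 > 0.8), which is the intended protection
against stutter and error false positives.

**Inherent error floor.** Even with error-free reads, a true heterozygote
can draw a binomially skewed read split: at depth d the probability that
one allele exceeds 80% of reads is 2·P(Binom(d, ½) > 0.8 d) (≈ 3×10⁻⁴ at
d = 30).  The "noiseless recovery" test therefore uses constant depth 30
and study-like heterozygosity, where the expected number of such
miscalls over 1,600 calls is ≈ 0.2; observing zero at the fixed test
seed verifies the pipeline adds no error of its own, not that the rule
is error-free at shallow depth.

## Diversity and differentiation

Per locus and population: A (alleles observed), Ae = 1/Σp², I = −Σp ln p,
Ho (observed heterozygote fraction among typed individuals), He = 1 − Σp²
(Nei's gene diversity; the unbiased 2n/(2n−1) form is emitted as `uHe`),
Fi = (He − Ho)/He.  Population rows are means across loci; Fi averages
only polymorphic loci (it is undefined at He = 0).  Missing genotypes are
dropped per locus (pairwise-complete).

**Hardy–Weinberg.** Chi-square goodness of fit over all k(k+1)/2 genotype
cells with expectations n·p² and 2n·p_i p_j, df = k(k−1)/2, no pooling —
reproducible degrees of freedom at the cost of asymptotic accuracy in
sparse cells; an exact test is a possible extension.  Monomorphic loci
and n < 5 are flagged untested.

**Null alleles.** EM under the standard model: one unobservable allele;
null heterozygotes present as apparent homozygotes, null homozygotes as
missing calls (optional `n_missing`).  The E step splits apparent
homozygote counts by conditional probability p/(p + 2p₀); the M step
re-estimates frequencies from expected allele copies; iteration stops
when the log-likelihood improves by < 1e-8 (cap 10⁵ iterations,
non-convergence flagged).  Verified against a grid-search ML oracle and
recovery of planted null frequencies.

**θST.** Weir & Cockerham's variance-component estimator, summed over
alleles and loci: θ = Σa / Σ(a+b+c) with the textbook a (among
populations), b (among individuals within populations) and c (within
individuals) for r = 2 samples.  Loci where either population has no
typed individuals, or n̄ ≤ 1, are skipped.  Estimates can be negative;
the pairwise-matrix writer can optionally floor them at zero, but raw
values are the default and are what the permutation test uses.
Significance: individuals are permuted across the two populations
(multilocus genotypes kept intact), p = (1 + #{θ* ≥ θ})/(n_perm + 1),
default n_perm = 999.  Permutation p-values verified uniform under the
null (KS test over 200 null datasets).

## Gene pools (DAPC)

**Encoding.** One column per locus × allele with dosage 0/0.5/1 (allele
copies / 2); missing genotypes are mean-imputed and columns centered, so
imputed cells carry no signal.  Mean imputation blurs structure when
missingness is high; the pipeline logs a caution above 10%.

**Number of clusters.** PCA scores (default: smallest number of PCs
explaining ≥ 90% variance) are clustered with k-means (20 restarts) for
K = 1..k_max and scored with BIC(K) = n ln(WSS_K/n) + K ln n.  The K is
chosen by the **diffNgroup elbow rule** (Ward-split of successive BIC
differences into steep-vs-flat groups, K at the last steep drop), not by
the arg-minimum: on allele-dosage data the BIC curve keeps decreasing
past the true K because k-means can always shave within-cluster variance
off discrete genotype classes, so the arg-minimum saturates at k_max
essentially always (measured 0/27 recoveries of a planted K = 4 versus
25/27 for the elbow rule).  The arg-minimum remains available
(`criterion="min"`).  Since no elbow rule can return K = 1, a
permutation pre-test first asks whether any multilocus structure exists:
individuals are permuted independently within each locus block (which
preserves every per-locus genotype distribution but destroys cross-locus
correlation), and K = 1 is reported unless the observed K=1→2 BIC drop
exceeds every null drop (5 replicates).

**Memberships.** Linear discriminant analysis on the retained PCA scores
(posterior probabilities = memberships; shrinkage LDA on singular
within-group covariance).  An optional randomization a-score is provided
for choosing the number of retained PCs when overfitting is a concern.

**Mixed genotypes.** Each site's "home" cluster is its modal assignment
(ties broken toward the globally larger cluster, logged).  An individual
is flagged iff its maximum membership goes to a foreign cluster with
probability > 0.5.  Flags are computed from site labels; regional-level
flags can be obtained by passing region labels instead.

## Directional migration networks

For each ordered pair (a, b), a hypothetical pool takes the per-locus
mean of a's and b's allele frequencies.  The differentiation between the
*recipient* b and the pool is converted to the migration estimate a → b:
m = (1 − d)/(2d) for G (Nei's G_ST from across-locus mean Hs, Ht) and D
(Jost's D, arithmetic mean of per-locus values with the two-deme n/(n−1)
correction), and Wright's island-model Nm = (1 − G)/(4G) for the Nm
index.  One-way flow drags the recipient toward the joint pool, so low
recipient-vs-pool differentiation signals high incoming migration.  The
directed matrix is normalized by its maximum (constant factors in the
transforms therefore cancel); zero-differentiation pairs are capped at
the matrix maximum before normalization, and edges with relative value
below the filter (default 0.35) are pruned.

Properties established on simulations, and their limits:

* the direction of *weak* planted one-way flow (m = 0.02 into the
  recipient, 100 generations of drift at Ne = 200; realized θ ≈ 0.09) is
  recovered in ≥ 95% of replicates with the G and Nm indices;
* under *strong* migration (m = 0.1 at Ne = 200) the demes equilibrate
  near panmixia (expected θ ≈ 1/(4Nem+1) ≈ 0.01) and donor and recipient
  become symmetric about their pool — no frequency-based method can
  recover direction there, and detection falls toward chance.  The
  directional signal requires migration weak relative to drift;
* Jost's D can *invert* the inferred direction under one-way flow: the
  recipient's elevated heterozygosity shrinks D's 1 − Hs denominator.
  D is emitted for completeness but G (default) or Nm should be used for
  directional inference.

**Bootstrap.** Individuals are resampled with replacement within
populations (default 100 replicates); per-edge support is the fraction of
replicates passing the filter.  Asymmetry of a pair is tested two-sided
at level α = 0.05: significant iff the (α/2, 1 − α/2) percentile interval
of m_ab − m_ba excludes 0.  Note the bootstrap conditions on the realized
allele frequencies: genuine drift-induced asymmetry in a "symmetric"
demography is (correctly) detected as significant; the calibration null
is two samples from one gene pool, where non-significance holds at the
nominal ≥ 95%.

## Synthetic data

The generator emulates the study design it is meant to test: 8 tri- and
tetra-nucleotide loci (synthetic reference flanks, 40 bp each side so
that every plausible allele's amplicon clears the 75 bp length filter),
multi-population samples with inbreeding (Fis as an identity-by-descent
mixture, matching E[Ho] = (1 − Fis)(1 − Σp²); study-scale values
0.16–0.36), divergence to a target F_ST via the Dirichlet F-model
(concentration p(1 − F)/F), and forward drift/migration frequency
simulation for planted gene flow.  Reads carry the full amplicon with
negative-binomial depth (default mean 40, dispersion 5;
dispersion = inf gives constant depth), ±1-repeat-unit stutter (default
0.05), per-base substitution error (default 0.005) and Gaussian Phred
scores (mean 35, sd 3, truncated to [2, 40]).

What the simulator does **not** model — and hence what passing tests do
not show about real data: flank SNPs/indels, partial-amplicon and
chimeric reads, multi-step stutter, per-cycle quality decay, locus-
specific amplification bias, and allelic dropout other than through the
modelled null-allele mechanism.

## Problem sizes and determinism

Default test problem sizes were chosen to make sampling noise small
relative to the tested effect while keeping the suite quick: n = 500 for
Fi/He recovery, 20 replicates for θ and migration-direction rates,
n = 50 per pool for K-selection, 199–999 permutations, and 60–100
bootstrap replicates.  Every stochastic component takes an explicit seed
(numpy Generator); identical parameters and seed reproduce byte-identical
FASTQ and CSV output, and the pipeline manifest records every seed and
threshold used in a run.
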