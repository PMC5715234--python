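# Methods

## Data model

Genotypes are diploid biallelic SNP calls stored as an alt-allele dosage
matrix (samples × loci) with values {0, 1, 2} and a distinguished missing
sentinel (−1), never a numeric zero.  Positions are 1-based (VCF
convention); all genomic intervals elsewhere in the package are half-open
[start, end).  Heterozygote dialects ("0/1", "1|0", "AT", "TA") all map to
dosage 1; phase is ignored throughout.  The minor allele is recomputed per
analysis scope, because MAF depends on the sample set being summarised.

The missingness filter removes loci whose missing fraction is *strictly*
greater than the threshold (default 0.20), so a locus missing in exactly
20% of samples is retained.  The filter is idempotent and reports input /
removed / retained counts and the retention percentage.

## Diversity statistics

For alt frequency p and q = 1 − p estimated over non-missing calls:
gene diversity He = 1 − (p² + q²); PIC = 1 − (p² + q²) − 2p²q² (the
Botstein measure reduced to two alleles — the convention of the PowerMarker
family of tools); observed heterozygosity = heterozygote fraction among
called genotypes.  He peaks at 0.5 and PIC at 0.375, both at p = 0.5; these
are the attainable range maxima for any biallelic panel.  Loci with no
called genotype in a subset are flagged undefined and excluded from means,
never zero-filled.  Pooled-group summaries are recomputed from pooled
samples, not averaged from subgroup summaries (pooling two diverged pools
inflates diversity, and the package reproduces that).

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (composite genotypic LD).  This is a deliberate
dialect choice: inputs are unphased, and for near-fully inbred lines the
composite estimator coincides with gametic r².  Significance uses the
standard allelic-association approximation χ² = n·r² on 1 df.  Decay is a
bin-resolution quantity: mean r² is computed in distance bins (default
500 kb) and the decay distance is the midpoint of the first bin below the
threshold (default r² = 0.1) after which the binned mean never rises back
above it; if the mean never crosses, the decay distance is reported as
beyond the observed range.  Under the null, E[r²] ≈ 1/n, which the test
suite checks by Monte Carlo.

## Relatedness

Rogers distance treats each individual as a per-locus allele-frequency
vector (dosage/2); for biallelic loci the per-locus term reduces to
|x_i − x_j| with x ∈ {0, ½, 1}, averaged over pairwise-complete loci.  The
allele-sharing distance 1 − shared/(2L) coincides with it for biallelic
SNPs; both tags are kept for provenance.

The Loiselle kinship coefficient is

    K_ij = Σ_l Σ_a [(p_ila − p_la)(p_jla − p_la) + p_la(1−p_la)/(n_l − 1)]
           / Σ_l Σ_a p_la(1−p_la)

with p_ila the individual allele frequency (dosage/2), p_la the reference
frequency, and n_l the number of alleles called at locus l.  Two choices
the estimator's description leaves open are fixed and documented here: the
reference sample is the full panel, and the negative-value truncation to
zero is applied per pair after summation across loci (not per locus).  K is
not rescaled to [0, 1] — values above 1 are legitimate for highly related
pairs.  For biallelic loci the two-allele sums share a factor of two that
cancels in the ratio, so the implementation uses the alt allele only; a
literal per-allele transcription serves as the test oracle.

Neighbor joining delegates to scikit-bio's Saitou–Nei implementation with
negative branch lengths clamped to zero.  Output is an unrooted newick
tree; no bootstrap.  The test oracle enumerates all unrooted topologies
(n ≤ 6), fits branch lengths by least squares, and checks that both the
enumeration optimum and the NJ tree reproduce the generating topology on
additive matrices.

## Structure

PCA operates on the mean-imputed, centered, optionally Patterson-scaled
(1/√(p(1−p))) dosage matrix; Patterson scaling is the default.
Monomorphic loci are dropped.  Axis signs are fixed by making each axis's
largest-magnitude locus loading positive, so results are reproducible and
invariant (exactly, not just up to sign) under sample reordering.

Bayesian admixture inference is out of scope; the package post-processes
its outputs.  Evanno's ΔK at interior K is mean_r |L_r(K+1) − 2L_r(K) +
L_r(K−1)| / sd_r L_r(K) over replicate log-likelihoods; it is undefined at
boundary K and where the replicate sd is zero.  Cluster-versus-origin
cross-tabulation maps each cluster to its majority origin and reports the
percentage of concordant samples.

## Differentiation

Per-locus differentiation uses the Weir–Cockerham (1984) two-level moment
estimator: variance components a (among populations), b (among individuals
within populations), c (within individuals), computed from per-population
sample sizes, allele frequencies and observed heterozygosities;
θ = a/(a+b+c).  Negative per-locus components are retained in sums and
per-locus θ may be negative (small-sample estimator).  Multilocus and
window estimates are ratio-of-sums Σa/Σ(a+b+c), never the mean of
per-locus ratios.  Sliding windows (default 100 kb window, 10 kb step) are
anchored at position 1 on every chromosome, membership is half-open, empty
windows are omitted, and the outlier rule flags windows at or above the
0.95 empirical θ quantile with all cutoff ties included.

AMOVA is the standard two-level distance-based decomposition on squared
Euclidean dosage distances, normalised per pair by the number of
pairwise-complete loci.  Φ_ST = σ²_among/(σ²_among + σ²_within); the
permutation P-value uses the add-one correction (1 + #{Φ_perm ≥ Φ_obs}) /
(B + 1) with a seeded generator, B = 1,000 by default.  On fully observed
inbred-line panels Φ_ST and multilocus θ agree within 0.01.

## Selection scans

**Frequency-difference t.**  With subpopulation alt frequencies f₁, f₂
from n₁, n₂ diploid individuals and f̄ = (f₁n₁ + f₂n₂)/(n₁ + n₂),

    t = (f₁ − f₂) / sqrt[(1/(2n₁) + 1/(2n₂)) · f̄(1 − f̄)]

referred to Student's t with 2n₁ + 2n₂ − 2 df (allele counts minus two;
the normal reference is available and differs only in the extreme tail at
these sample sizes).  Tail probabilities are computed in log space, so
−log₁₀P beyond 300 is finite and accurate; the suite validates the tails
against an arbitrary-precision incomplete-beta oracle to 3 significant
figures.  Population-specific alleles are loci where one allele (either
orientation) has frequency exactly zero in one pool, is present in the
other, and the t test passes α = 0.001 — a singleton allele at these
sample sizes fails the significance arm by design.

**EigenGWAS.**  The GRM is ZZᵀ/m with z = (dosage − 2p)/√(2p(1−p)),
missing dosages mean-imputed and monomorphic loci excluded.  The focal
eigenvector (default: the first of the top 10) is regressed on each
locus's dosage; χ² = (slope/se)².  The genomic-control factor is
λ_GC = median(χ²)/0.45494 and corrected P-values (PGC) come from χ²/λ_GC
on 1 df, again with log-space tails.

A calibration property worth stating explicitly: under *no* structure the
focal eigenvector is the top principal axis of pure sampling noise, so the
per-locus χ² inflation equals the bulk spectral edge (1 + √(n/m))² of the
standardized genotype matrix — about 1.73 at n = 200, m = 2,000 — rather
than 1.  λ_GC therefore concentrates at that edge under the null at any
realistic n/m ratio, and the genomic-control division removes exactly this
factor (the median corrected χ² is 0.455 by construction).  The test suite
asserts this law; an idealised expectation of λ_GC ≈ 1 under the null
holds only in the m ≫ n limit.

**Candidate ranking.**  Each locus receives descending ranks under the
three statistics (window/locus θ, t-test −log₁₀P, EigenGWAS −log₁₀PGC);
the combined key is the best of the three ranks with ties broken by
(chrom, pos).  Annotation overlap uses half-open interval containment and
is checked against a brute-force all-pairs scan.

## Synthetic data generator

The generator follows the Balding–Nichols model: ancestral frequency
p ~ Uniform(0.05, 0.95) per locus; each population's frequency is an
independent Beta(p(1−F)/F, (1−p)(1−F)/F) draw, so the single parameter F
is the expected FST.  Defaults are the study conditions the package is
designed around: n₁ = 277 and n₂ = 300 diploids, 5,195 loci on 20
chromosomes of 50 Mb, background F = 0.1933, inbreeding 0.95 (cultivar
panels are near-fully selfing; observed heterozygosity lands near 0.07),
5% admixed individuals (each locus drawn from the 50/50 frequency
mixture), and configurable missingness applied independently per call.

Planted outlier loci emulate divergent selection.  Two modelling choices
matter and are deliberate: (i) planted loci draw their ancestral frequency
from Uniform(0.25, 0.75), because selection of this kind acts on standing
variation at intermediate frequency; (ii) the two populations' Beta draws
(at selected_F, default 0.8) are conditioned by rejection sampling to
opposite sides of the ancestral frequency.  Without the conditioning,
half of high-F loci drift toward the *same* allele in both pools and are
undetectable in principle; with it, planted loci show frequency gaps of
roughly 0.7–0.95, the regime of real top selection candidates, and both
the top-5% FST window scan and the EigenGWAS tail recover ≥80% of them.

What the generator does **not** model: linkage disequilibrium between loci
(loci are exchangeable given their frequencies, so LD decay is tested on
separately constructed correlated fixtures, and passing LD tests says
nothing about real decay distances), genotyping-error structure, related
individuals/pedigrees, and chromosome-specific marker density.  Passing
recovery tests therefore demonstrates estimator correctness under the
divergence model, not reproduction of any real panel's LD or kinship
profile.

## Numerical choices and problem sizes

All stochastic routines take explicit seeds and consume a single numpy
Generator.  The acceptance script simulates 277 + 300 × 5,000 loci (the
study's sample sizes at a marker count giving ~0.005 Monte-Carlo sd on
multilocus θ) and uses 199 AMOVA permutations; the test suite uses panels
of 40–600 samples and 100–5,000 loci chosen so each check's Monte-Carlo
error is well inside its assertion tolerance.  Ties at the window-outlier
cutoff are all flagged; windows beyond the last locus of a chromosome are
not enumerated; degenerate inputs (empty panels, monomorphic-only loci,
all-missing loci, zero-sd Evanno replicates, asymmetric distance matrices)
raise or flag rather than silently producing numbers.

## Known limitations

Real-data headline quantities that depend on the undeposited genotype
calls of any particular panel (mean diversity levels, LD decay distances,
specific candidate loci) are context, not targets: the package reproduces
the *methods*, and its tests verify them on generated data with known
truth.  Multi-allelic markers, imputation, phasing and Bayesian admixture
inference are out of scope.
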