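# Methods

This note documents the statistical models behind `radpop`, the defaults
and tolerances it uses, what the synthetic-data generators do and do not
emulate, and the design choices made where the methodology was open.

## Scope and data model

`radpop` operates downstream of variant calling: its substrate is a
matrix of biallelic SNP dosages (0/1/2 copies of the alternate allele,
with a missing code) for a cohort of individuals, carrying per-locus
metadata (scaffold, 1-based position, alleles) and optionally a
per-genotype read-depth matrix. VCF v4.2 is the only genotype
interchange format; half-calls (`0/.`) are treated as missing because
nothing downstream can use a single known allele. Alt-allele dosage is
the stored code; minor-allele orientation is applied inside each
statistic, so codes are stable under filtering.

## Filter cascades

Three named cascades reproduce the common pattern of tailoring one
jointly-called SNP set to different analyses:

* **A (LD decay)** — per-genotype depth mask (keep depth in [8, 30],
  inclusive), restriction to the 100 longest scaffolds, removal of loci
  with any Mendelian incompatibility, restriction to an explicit list of
  focal-population adults, MAF ≥ 0.1, call rate ≥ 0.5, Hardy–Weinberg
  exact p ≥ 0.001.
* **B (population structure)** — restriction to unrelated pups plus the
  other populations, MAF ≥ 0.05, call rate ≥ 0.99, per-population HWE
  (a locus is dropped if it fails in *any* population), VIF pruning
  (window 50 SNPs, step 5, threshold 2).
* **C (inbreeding)** — drop individuals with > 90 % missing data, depth
  mask, Mendelian filter, focal-population list, MAF ≥ 0.05, call rate
  ≥ 0.7, HWE, VIF pruning.

Conventions that matter: every "less than" threshold is strict (a locus
exactly at the threshold survives); per-locus statistics are recomputed
after every stage; population membership and the adult/pup keep-lists
are explicit sample metadata, never inferred from genotypes. Each stage
is idempotent and emits an audit record (loci/individuals before and
after, parameters), so a cascade yields a complete filter trail.

**HWE exact test.** The two-sided exact test conditions on the observed
allele counts and sums the probabilities of all heterozygote counts no
more probable than the observed one (probability-ordering rule, no
mid-p). This matches the behaviour of the standard genotype-QC tools.
The implementation enumerates heterozygote counts of the correct parity
in log space; it is validated against full combinatorial enumeration for
every configuration with N ≤ 10.

**Mendelian checks.** A (child, locus) combination is an error iff the
child genotype is impossible under Mendelian transmission given the
available parental genotypes: with both parents typed, the child must be
expressible as one gamete from each (the full 27-combination trio table
is enumerated in tests); with one parent typed, only opposite
homozygotes (parent 0 with child 2, parent 2 with child 0) are
impossible. Loci with ≥ 1 error are removed.

**VIF pruning.** Within a sliding window, a SNP's variance inflation
factor is 1/(1 − R²), with R² its squared multiple correlation on the
other window SNPs, computed from the pairwise-complete correlation
matrix via r′S⁻¹r with a pseudo-inverse, so exact collinearity gives
infinite VIF and monomorphic SNPs VIF 1. While any VIF exceeds the
threshold the largest (lowest index on ties) is removed and VIFs
recomputed; the window then advances by the step. Because a removal in
one window can change another window's composition, sweeps repeat until
a full pass removes nothing — this guarantees the advertised
post-condition that no window of the surviving set exceeds the
threshold. No imputation is used anywhere; all correlations are
pairwise-complete.

## LD decay

Pairwise r² is computed for all same-scaffold SNP pairs within a
distance cap (default 500 kb). Two estimators are provided:

* **EM (default)** — maximum-likelihood two-locus haplotype frequencies
  from unphased genotype counts, iterating the expectation of the
  coupling/repulsion split of double heterozygotes;
  r² = D²/(p_A q_A p_B q_B). This is the estimator usual genotype-based
  LD tools report for unphased data.
* **composite** — squared Pearson correlation of dosage vectors over
  pairwise-complete individuals; robust, and identical to the EM value
  when no double heterozygotes are present.

Observed r² against physical distance d is fitted with the expected r²
under drift–recombination equilibrium (Hill & Weir),

    E(r²) = [(10+ρ)/((2+ρ)(11+ρ))] · [1 + ((3+ρ)(12+12ρ+ρ²))/(n(2+ρ)(11+ρ))],

with ρ = C·d and n the number of gametes scored. The single parameter
C ≥ 0 (per bp) is estimated by bounded least squares on all pairs
(unbinned); the start value comes from a coarse log-grid search over
[1e-7, 1e-2] per bp so the result does not depend on solver defaults.
n defaults to 2 × the number of individuals and is exposed as a
parameter. The curve's large-ρ asymptote is 1/n; fitted curves are
strictly decreasing, so decay distances for r² thresholds (e.g. 0.5,
0.2) are found by bisection, and thresholds outside (1/n, E(r²)|ρ=0)
return a "not reached" sentinel. The "background level" is
operationalized as the mean r² beyond a user-chosen distance (default
400 kb) and can be compared with the 1/n floor; for dosage-based r² the
finite-sample floor is closer to 1/(N−1) for N individuals.

## Inbreeding and identity disequilibrium

Four per-individual coefficients are computed, each averaging over the
loci typed in that individual, with sample allele frequencies:

* sMLH — proportion of heterozygous loci divided by the mean population
  heterozygote frequency of the same loci; mean exactly 1 under
  complete data.
* f1 (variance of additive genotypes) — (x − 2p)²/(2pq) − 1.
* f2 (excess homozygosity) — 1 − x(2 − x)/(2pq).
* f3 (correlation of uniting gametes) — [x² − (1+2p)x + 2p²]/(2pq),
  which up-weights rare-allele homozygotes.

Each of f1–f3 has expectation f under the inbreeding model when p is
known. Because p is estimated from the same sample (there is no
external reference panel), a plug-in bias of order 1/N remains
(empirically ≈ −(1+3f)/2N); the simulation checks therefore use cohorts
of several hundred individuals, where the bias is inside Monte-Carlo
resolution. This is a property of the estimators as defined, not of the
implementation.

Identity disequilibrium is estimated by the multilocus ratio-of-sums

    ĝ2 = [ (1/N) Σ_i Σ_{l≠m} h_il h_im ] /
         [ (1/(N(N−1))) Σ_{i≠j} Σ_{l≠m} h_il h_jm ] − 1,

with h the 0/1 heterozygosity indicator and all sums restricted to
non-missing entries (coding missing as 0 is algebraically identical).
Under per-individual inbreeding f, ĝ2 is consistent for
var(f)/(1 − E f)², the quantity that also equals the expected squared
correlation between an inbreeding estimate f̂ and realized inbreeding
f* after division by σ²(f̂): r²(f̂, f*) = g2/σ²(f̂). The estimator is
validated against a direct quadruple-loop evaluation on small matrices
(including missing data).

Uncertainty: a percentile 95 % bootstrap over individuals (default
1000 replicates; degenerate resamples are redrawn and counted), and a
permutation p-value whose null shuffles each locus column independently
across individuals — preserving per-locus heterozygosity and
missingness while destroying within-individual correlation — with
p = (1 + #{ĝ2_perm ≥ ĝ2_obs})/(n_perm + 1). Pairwise correlations
between the four coefficients are reported with sMLH sign-flipped so
all measures share the inbreeding orientation; the convention is
recorded in the result's metadata.

## Population-structure summaries

PCA of the dosage matrix mean-imputes missing calls per locus, centers
(optionally standardizes) and uses a full SVD; eigenvalues and percent
variance are reported per axis and axis signs are arbitrary. The
clustering MCMC itself is out of scope: its run table (K, run, ln
probability) is summarized by per-K mean and sample sd (ddof = 1) and
by the Evanno second-difference statistic
ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(K), defined only at interior K with
positive sd. Whether the original ΔK used sample or population sd is
ambiguous in the literature; sample sd is used here and documented.

## Synteny profiling

Pairwise MAF alignments are parsed with Biopython; each block records
both sequences' forward-strand half-open coordinates, the number of
aligned (both non-gap) columns and matched columns. By LAST convention
the database/target sequence comes first in each block; a `query_first`
switch covers the opposite layout. Blocks can be filtered by query span
(strictly greater than a minimum, default 5 kb). Per-scaffold profiles
sum query-side span per target chromosome — overlapping blocks are
counted as-is, mirroring "total alignment length" — and classify each
scaffold as *exclusive* (one target), *majority* (top fraction strictly
above 0.9) or *split*. Divergence is pooled, not averaged per block:
1 − Σmatched/Σaligned, over substitution columns only (gap columns are
excluded), a convention that is documented because alternative
tool-specific definitions exist.

## Synthetic data

The generators provide the statistical structure the analyses assume,
with truth returned alongside:

* **Inbred genotypes** — per locus and individual, autozygous with
  probability f*_i (homozygote by allele frequency), otherwise a
  Hardy–Weinberg draw; f* comes from a constant, a two-point mixture
  (default {0, 0.25}, giving theoretical g2 ≈ 0.0204) or a Beta
  distribution. Autozygosity is independent across loci — there are no
  runs-of-homozygosity tracts, which is sufficient because no statistic
  in this package is tract-based.
* **Structured populations** — Balding–Nichols: population-specific
  frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) around a shared ancestral p,
  binomial genotypes; no migration or admixture model.
* **LD haplotypes** — a forward Wright–Fisher pool (default 100
  haplotypes) evolved with per-generation crossover between adjacent
  loci at distance-proportional rates, then paired into diploids; the
  phased pool is returned as the r² oracle. Drift can fix loci; such
  loci are skipped by the r² estimators, as with real monomorphic
  sites. A coalescent would be more efficient at scale but is
  unnecessary at desk scale.
* **Trios** — one gamete per parent; optional injected errors replace a
  child genotype with one incompatible with its parents (impossible
  only when both parents are heterozygous, where every child genotype
  is legal).
* **Depth/missingness** — gamma-Poisson (negative binomial) depths and
  uniform missingness.

All generators are bit-reproducible given their seed. What they do
*not* emulate: genotyping error outside the injected Mendelian errors,
allele-specific depth bias, linked selection, demographic history, or
ROH structure — so passing tests demonstrate correctness of the
statistics under their own model assumptions, not robustness to every
artifact of real RAD data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which each statistical statement is resolvable:
g2 theory identity at 200 individuals × 2000 loci (Monte-Carlo
tolerance 0.01 absolute); decay-rate recovery at 5000 pairs with
Gaussian noise sd 0.05, 20 replicates, median relative error ≤ 10 %;
permutation-test calibration over 200 null replicates of 99
permutations (binomial 3σ band around 5 %); estimator-bias checks at
400-individual cohorts. EM iterations stop at a haplotype-frequency
change below 1e-12 (cap 200 iterations); the decay fit caps at 2000
function evaluations and reports a convergence flag; bisection for
decay distances runs 200 halvings. Ties in VIF removal take the
lower-index SNP; scaffold-length ties in the longest-N restriction are
broken by label order.

## Known limitations

* The ĝ2 estimator's missing-data handling restricts sums to complete
  combinations; it is exact on complete data (brute-force verified) but
  is not claimed to replicate any particular package's reweighting
  under missingness.
* The permutation null for g2 is a stated construction, chosen because
  it preserves locus-wise heterozygosity and missingness; other nulls
  (e.g. genotype-level shuffles) would test subtly different
  hypotheses.
* F̂ estimators inherit the O(1/N) sample-frequency plug-in bias noted
  above.
* The VIF sweep-to-fixpoint removes at least as many SNPs as a single
  pass; tools that make one pass may retain slightly more loci.
* Per-population HWE filtering uses a fixed α with no multiple-testing
  correction, matching standard QC practice rather than inferential
  best practice.
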