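# Methods

`msatpop` implements the population-genetic analysis arc for codominant
microsatellite (SSR) genotypes sampled from discrete populations grouped
into regions: diversity and fixation statistics, between-population
structure, bottleneck detection, fine-scale spatial genetic structure, and
ABC-based demographic scenario choice, plus the synthetic-data generators
used to verify every stage.

## Data model

Genotypes are unordered pairs of positive integer allele sizes per
individual x locus; a call is either fully observed or fully missing
(sentinel `0`).  Individuals belong to exactly one population; populations
may carry a regional group label.  Missing calls are excluded from all
denominators.  Individuals with more than 50% missing loci are retained but
flagged; exclusion is an explicit pipeline option (off by default), since
no principled default exists without knowing the genotyping failure mode.

## Diversity and F-statistics

Per population x locus, with allele frequencies `p`:
`Ne = 1/Σp²`, `He = 1 − Σp²`, `I = −Σ p ln p`, and `Ho` the observed
heterozygote fraction.  `He` is deliberately the plain (biased) estimator —
the convention of the spreadsheet tools this report format mirrors — so
`He = 1 − 1/Ne` holds exactly; an unbiased `2N/(2N−1)` variant exists where
noted (the bottleneck test uses unbiased `He` throughout, following the
test's own convention).

Per-locus fixation indices use the Nei heterozygosity formulation:
`Hs` is the unweighted mean within-population `He`; `Ht = 1 − Σ p̄²` with
`p̄` the unweighted mean frequency across populations; then
`Fis = 1 − Ho/Hs`, `Fit = 1 − Ho/Ht`, `Fst = 1 − Hs/Ht`.  This makes the
hierarchical identity `(1 − Fit) = (1 − Fis)(1 − Fst)` an algebraic fact,
verified to 1e-9 on every report.  Gene flow is the island-model
`Nm = (1 − Fst)/(4 Fst)`; summary rows are unweighted arithmetic means of
per-locus values (so the mean `Nm` is the mean of per-locus `Nm`, not
`Nm` of the mean `Fst`).  Loci monomorphic overall have `Ht = 0`; their
F-statistics are reported missing and excluded from means.

`F′st = Fst / Fstmax`, where `Fstmax` recomputes `Fst` after relabelling
every allele population-uniquely — within-population genotype structure
(hence `Hs` and `Ho`) is preserved while allele sharing between populations
is abolished.  `F′st ≥ Fst` whenever both are defined.

Hardy–Weinberg testing is a Monte-Carlo exact test conditioning on allele
counts: the observed gene copies are randomly re-paired, and the p-value is
the proportion of resampled genotype arrays whose Levene conditional
probability is at most the observed one (add-one corrected), with the
Monte-Carlo standard error reported.  Default 10,000 iterations with an
explicit seed; a single resampling chain is used rather than batched
chains — the estimand (the exact-test p) is identical.  Whether per-locus
significance should pool populations is left to the caller; the report
works per population x locus.

Null-allele screening uses the closed-form Chakraborty
`r = (He − Ho)/(He + Ho)` and Brookfield-1 `(He − Ho)/(1 + He)` estimators,
flagging cells where the estimate exceeds 0.05 *and* the homozygote excess
is HWE-significant.

## Distances, ordination, AMOVA, Mantel, ΔK

Nei's (1972) standard distance `D = −ln(Jxy/√(Jx·Jy))` sums the identity
terms over loci before the ratio; population pairs sharing no alleles have
infinite `D`, capped at 10 (configurable) and flagged.  Neighbour joining
follows Saitou–Nei; a negative branch length is clamped to zero with the
deficit transferred to its sister so the joined pair's path length is
preserved.  PCoA Gower-centres `−D²/2`; negative eigenvalues are reported
but excluded from coordinates and variance proportions.

AMOVA works on squared genotypic distances between individuals
(`d² = ½ Σ_a (c_ia − c_ja)²` over allele counts, summed over loci, with
pairwise-available-loci rescaling for missing data), partitioned
region / population-within-region / individual by the standard moment
equations with unbalanced-design coefficients.  Raw components may be
negative; they are clamped to zero for percentage reporting but kept raw in
the machine report.  Permutation significance: individuals among all
populations (Phi_ST), individuals among populations within regions
(Phi_SC), whole populations among regions (Phi_CT).  A conventional
df layout (a−1, b−a, N−b) is used.

The Mantel test correlates upper-triangle entries, permutes the labels of
one matrix, and reports the one-sided p (proportion of permuted r at least
the observed, add-one corrected) plus the least-squares line.  It is
implemented directly (rather than through a library call) so that the
permutation stream is seedable; the correlation matches scikit-bio's
`mantel` to machine precision in the test suite.  Geographic distances are
haversine on a 6371-km sphere (between sites) or Euclidean metres (within
a site).

Evanno's ΔK takes replicate clustering log-likelihoods per K and computes
`mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd(L(K))` for interior K; a zero
replicate SD yields an infinite ΔK, which is flagged rather than silently
dropped.

## Bottleneck detection

The heterozygosity-excess test compares, per polymorphic locus, the
observed unbiased `He` with the distribution of equilibrium `Heq`
conditional on the observed allele count `k` and gene-copy number `n`.
`Heq | k` is simulated with a single-population Kingman coalescent and a
two-phase mutation model: single repeat step with probability `p_single`
(default 0.7), otherwise a geometric multi-step jump parameterised by its
variance `sigma2_geom` (default 30) — common settings for this test family,
exposed as parameters since applications rarely agree on exact values, so
p-values are interpreted directionally.  θ is calibrated by log-bisection of the
simulated expected allele count, bracketed by the closed-form
infinite-alleles solution (stepwise homoplasy always demands θ at or above
the IAM value), and replicates are accepted by rejection on the realised
`k` (ceiling 200x the replicate budget, then an error).  The conditional
simulator reproduces msprime's SMM conditional `Heq` distribution within
Monte-Carlo error; note that strict SMM yields the *highest* conditional
`Heq` at fixed `k` and IAM-like models the lowest — which is exactly why
analysing SSR data under IAM produces spurious excess.

Across loci, a one-sided Wilcoxon signed-rank test on
`DH = (He − E[Heq])/SD[Heq]` asks whether `He` systematically exceeds
`Heq`; exact for ≤25 loci, normal-approximated with continuity correction
above.  The mode-shift diagnostic bins pooled allele frequencies into ten
classes `(0,0.1], …, (0.9,1]` and calls the distribution L-shaped iff the
lowest class holds the strict maximum.

The test's type-I error on matched equilibrium simulations is close to but
slightly above the nominal 5% — repeated 200-dataset calibrations land in
the 6–10% range depending on the stream.  The mild anticonservatism is
expected when the `Heq` moments are estimated from a finite replicate
budget (200 in the calibration runs; 1000 by default) and when the
observed-data mutation model is only approximately matched; it is
documented rather than corrected, since the test is used directionally.

## Fine-scale spatial genetic structure

Pairwise kinship uses the Loiselle estimator with the population's own
allele frequencies as reference: per locus,
`Σ_a (x_ia − p_a)(x_ja − p_a) + Σ_a p_a(1−p_a)/(n_l − 1)` over
individual allele frequencies `x ∈ {0, ½, 1}` with `n_l` gene copies, and
multilocus values as the ratio of summed numerators to summed
polymorphism-index denominators `Σ_a p_a(1−p_a)` over commonly typed loci
(this weights loci by polymorphism).  Loiselle is the default for its
robustness to rare alleles; the estimator choice matters less than the
reference-frequency choice, which is within-population here to match
per-population analyses.

Distance classes default to the field scheme (5 m steps to 20 m, 10 m to
50 m, one class to 100 m, 100 m steps to 600 m, truncated at the site's
maximum pair distance); an optional balanced mode redraws bounds at pair
quantiles so counts are equal — the fixed break scheme and the
constant-pair-count requirement conflict, so both are offered with the
fixed breaks as default.  Envelopes permute individual locations (1,000
default) and take the 2.5/97.5 percentiles of per-class means.

`b_LF(d)` is the least-squares slope of per-pair kinship on ln(distance)
over pairs (not class means — the convention of the standard software);
pairs at zero distance are excluded from the regression.  Its significance
permutes locations (two-sided on |b|).  `F(d1)` is the first class's mean
kinship and `Sp = −b / (1 − F(d1))`, an identity the code maintains to
machine precision.

The dispersal-asymmetry test fits a cubic in `ln d` to the residuals of the
class-mean correlogram around the `b_LF(d)` line and evaluates the
curvature `k = 2c + 6·d·ln(d1)` at the mean distance of the first class:
`k > 0` (concave at short range) indicates seed dispersal more restricted
than pollen dispersal, otherwise the reverse or no restriction.

## ABC demographic inference

Scenarios are deme trees with splits, size changes, and optional constant
backwards migration; parameter priors are uniform.  The simulation engine
is a structured coalescent (competing exponentials over per-deme
coalescence and migration rates, with timed events applied in order)
feeding a generalised stepwise mutation model: per-branch Poisson mutations
whose step magnitude is geometric with parameter `gsm_p` (prior U[0, 0.3]),
reflected at one repeat.  Mutation rate per locus is drawn per dataset from
U[1e-4, 1e-3] (mean 5e-4).  The engine matches msprime's summary
distributions on a fixed two-deme scenario within Monte-Carlo error (test
suite); msprime is not used here because the reference table needs tens of
thousands of small simulations where per-call overhead dominates.

The three divergence-direction scenarios are parameterised so the direction
is identifiable in principle: when group B buds off group A at `t1`, the
ancestral population *is* A — A's size parameter governs both A's recent
diversity and all deep coalescence — whereas the common-origin scenario S3
gives the ancestor an independent size NA.  Summaries per group and pooled:
mean allele count, mean unbiased He, mean allele-size variance, mean
M-ratio; between the first two groups: Nei-style Fst, shared-allele
distance, Goldstein's (δμ)², and each group's private-allele fraction (the
direction-sensitive statistic: a recently derived group carries mostly a
subset of its source's alleles).

Scenario choice simulates a reference table (desk default 50,000 datasets,
a deliberate reduction of the 10^6-scale reference tables used in
production analyses), retains the
1% nearest the observed summaries in MAD-scaled Euclidean distance, and
estimates scenario posterior probabilities by multinomial logistic
regression on the retained set (direct rejection proportions are reported
alongside).  Parameters of the winning scenario get the standard local
linear regression adjustment, clipped to the prior box.  Generations
convert to years at 5 years per generation (configurable).

**Identifiability caveat.**  S1 and S2 differ only in which group's size
parameter persists beyond `t1`, and S3 *nests* both (NA close to either
recent size reproduces them exactly).  At desk scale — tens of individuals
per group and 10–14 loci — a flexible classifier trained on the full
reference table separates the three scenarios well below the levels that
hundreds of individuals would support, and pseudo-observed datasets
generated under S1 are frequently absorbed by the nesting S3.  The
scenario-recovery calibration in the acceptance suite therefore measures
and reports an honest recovery rate at the stated desk scale rather than
guaranteeing a high one; the directional question (S1 vs S2) is
considerably easier than rejecting the nesting alternative.  MIGRATE-style
gene-flow model selection is represented structurally as ABC scenarios with
and without migration — a methodological substitution, not a reproduction
of marginal-likelihood machinery.  DS7–DS9's intermediate sizes reuse the
present-size prior bounds for lack of better-motivated ones.

## Synthetic data generators

*Island model* (msprime): `n` demes of diploid size `N` exchanging migrants
at rate `m`, optionally grouped into two regions whose demes merge into
regional ancestors and then a common ancestor; SMM or TPM mutations on a
bounded allele ladder (1–400 repeats, root at the midpoint).  Ground truth
(`Nm = N·m`, group labels) is returned alongside.  Defaults (20 demes in a
9+11 regional split, 14 loci, mutation rate 5e-4) mirror the sampling
design the statistics expect.

*Bottleneck histories* (msprime): single population with piecewise-constant
size, `(time, size)` schedule backwards from the present.

*Spatial model* (forward, own code): individuals on a square arena with
non-overlapping generations at fixed capacity.  Offspring are clonal with
probability 0.3 (placed within 10 cm of the parent, mirroring a field
protocol that avoids sampling ramets closer than that; `thin_ramets`
optionally applies the same rule to simulated samples), otherwise sexual:
the father is drawn by a Gaussian pollen kernel (σ_p, default 50 m),
selfing occurs at rate 0.3 with 80% of selfed seed aborted (a partially
self-sterile, strongly clonal perennial), and the seed disperses from the
mother by a Gaussian seed kernel (σ_s, default 5 m).  Single-step mutation
at 5e-4 per gamete, reflecting at one repeat.  Non-overlapping generations
are a simplification of perennial demography, and the kernels are Gaussian
by default where the real dispersal kernels are unknown (an exponential
option exists in the config surface of the SGS comparisons); passing tests
on this generator demonstrates the statistics recover *designed* structure,
not that real orchid data would behave identically.  Capacity defaults are
arbitrary in the absence of census sizes and are flagged as such.

## Problem sizes and budgets

The test and acceptance workloads use deliberately reduced problem sizes
chosen to keep the full verification cycle at desk scale: equilibrium
bottleneck calibration at 200 replicates with a shared conditional-`Heq`
cache, spatial SGS recovery at 50 forward simulations of ~80 plants,
Mantel/SGS null calibrations at 200 replicates with 99–199 permutations,
and one shared 50,000-row ABC reference table.  These sizes are the
package's own verification conditions; all are parameters, not constants.

## Known limitations

- GenAlEx-dialect parsing is tolerant by design; exotic layout variants
  (multi-sheet exports, trailing annotation rows) need the plain dialect.
- AMOVA assumes the two-level design when region labels exist; deeper
  hierarchies are out of scope.
- The HWE Monte-Carlo test is exchangeable-chain only; Fisher-method
  pooling across populations is left to the caller.
- The ABC engine supports up to a handful of demes with piecewise-constant
  sizes and constant migration; continuous growth and admixture events are
  not modelled.
- The bottleneck test conditions on the realised allele count by rejection;
  loci where `k` is close to `n` can exhaust the attempt ceiling and error
  rather than silently degrade.
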