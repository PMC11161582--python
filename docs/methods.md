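# Methods

This note records the statistical models behind `pangotrace`, the defaults
and their rationale, what the synthetic generator does and does not
emulate, and the numerical choices that a user of the results should know.

## Data model

Genotypes are unordered pairs of integer allele codes (fragment sizes in
bp, stored sorted); 0 encodes a missing call and a half-missing pair is
normalised to missing, since a single scored allele of a diploid genotype
is not interpretable.  No binning or repeat-unit normalisation is applied
to allele codes — the pipeline analyses scored sizes as given.  Two file
dialects are supported losslessly: the GenAlEx codominant CSV (header with
locus/sample/population counts, two columns per locus, 0 = missing) and a
long-format TSV (one row per sample × locus) that also carries sample
class, coordinates and metadata.  Individuals typed at fewer than 75% of
loci are dropped by the pipeline default (`min_completeness = 0.75`,
i.e. ≥ 15 of 20 loci in the default panel).

Coordinates are WGS84 decimal degrees.  Geographic distances default to
great-circle km (haversine); a planar-Euclidean mode (km-per-degree at the
mean latitude) is provided because field studies often report "Euclidean"
distances without stating a projection.  At the few-hundred-km scale of a
regional trade study the two differ by under ~2%.

## Diversity and differentiation

Expected heterozygosity is Nei's gene diversity He = 1 − Σpᵢ² from sample
allele frequencies; uHe applies the 2n/(2n−1) small-sample correction
with n the typed genotypes at the locus; Ho is the heterozygous fraction.
Population summaries average over typed loci.

Allelic richness uses hypergeometric rarefaction,
A_R(g) = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)], standardized by default to g = twice
the smallest per-locus typed sample across populations (the FSTAT
convention), so that sample-size differences do not masquerade as
diversity differences.

F_IS and F_ST are Weir & Cockerham (1984) variance-component estimators,
multilocus by summing components over alleles and loci; loci with missing
data contribute their complete cases.  F_IS significance comes from
shuffling gene copies among individuals within the population (one-tailed
for heterozygote deficit); pairwise F_ST significance from permuting
individuals between the two populations.  All permutation p-values use the
add-one rule p = (b+1)/(m+1) and therefore lie in (0, 1].  Defaults:
10,000 permutations for F_ST and Mantel, 1,000 LD randomizations,
Bonferroni for multiple testing.  HWE deviation defaults to the chi-square
goodness-of-fit on genotype counts with df = k(k−1)/2; a Monte-Carlo exact
variant (shuffling gene copies) is provided for sparse tables.  Null-allele
screening reports the Chakraborty and Brookfield-1 moment estimators and a
Monte-Carlo homozygote-excess p-value that compares the observed
homozygote count with its HWE distribution given the sample frequencies —
a deliberate simplification of Micro-Checker's allele-size-class version,
adequate for flagging loci but not for size-dependent artefact diagnosis.

Isolation by distance is a Mantel test: Pearson correlation of off-diagonal
entries under row/column permutation of one matrix.  The individual-level
genetic distance is the Cavalli-Sforza & Edwards chord distance on
allele-dosage profiles, d_l = √(1 − Σᵢ √(xᵢyᵢ)) averaged over mutually
typed loci.

## Individual identification

pgen multiplies per-locus genotype probabilities with an inbreeding
adjustment (p² + fp(1−p) for homozygotes, 2pq(1−f) for heterozygotes);
alleles absent from the reference pool receive the floor frequency
1/(2N+1) so market genotypes never get probability zero.  psex uses the
binomial form 1 − (1 − pgen)^(n−1), evaluated via log1p/expm1 because
forensic pgen values underflow the naive expression.  The identity indices
are PI = 2a₂² − a₄, PIsibs = ¼ + ½a₂ + ½a₂² − ¼a₄, and the unbiased PI
estimator with n = sampled gene copies and denominator (n−1)(n−2)(n−3);
this convention was verified by simulation to be unbiased (cohort mean
equals true PI), and uPI → PI as n → ∞.  Reference (not market) individuals
supply the frequencies by default.  `min_loci_for_pi` orders loci by
ascending per-locus PI and reports the smallest panel whose cumulative
product crosses the threshold (0.01 by default, the conventional forensic
bound).

## Private-allele tracing

For a set S of reference populations, the expected number of alleles
private to population j in subsamples of g gene copies is

E[private_j] = Σᵢ [1 − Q_{ji}(g)] · Π_{k≠j} Q_{ki}(g),
Q_{ki}(g) = C(N_k − N_{ki}, g) / C(N_k, g),

the generalized rarefaction used by allele-diversity software.  The unit
of g defaults to diploid individuals (2g gene copies), matching the
convention of rarefying "2 to 5 individuals, 5 being the smallest
population"; a gene-copy mode exists.  An exact-arithmetic path
(`exact=True`, `fractions.Fraction`) supports formula verification against
brute-force subset enumeration.

Locus selection keeps (locus, population) pairs with expected private
count > 0.4 at g\* = 5 whose last rarefaction step is not declining by more
than `slope_tolerance = 0.01` — the threshold interprets "private allele
frequency > 40%" as the rarefied expected count, and the tolerance
quantifies "plateau or increasing trend", for which no numeric rule exists
in common practice; both are configurable.  Loci where any population has
fewer than g\* typed individuals are excluded from rarefaction rather than
lowering g\*.  Candidates are cross-filtered against alleles observed in
exactly one reference population; the resulting panel maps each (locus,
allele) to a unique source.  A market or seizure individual is assigned to
a source if it carries ≥ 1 panel allele; carriers of panel alleles from
several sources are reported with a conflict flag, and the summary matrix
counts non-conflicted assignments by default.  Missing genotypes at panel
loci simply contribute no evidence; nothing is imputed.

Tracing validity rests on the panel alleles being truly private.  Alleles
can be *sampling-private* — observed in one population only by chance —
and these produce occasional misassignments (the worked example shows
172/176 agreement); with strictly private markers the assignment precision
is exactly 1 by construction, which the test suite verifies.

## Bottleneck test

For each polymorphic locus the observed unbiased gene diversity is
compared to its mutation-drift-equilibrium distribution conditional on the
observed allele count k and sample size.  The conditional distribution is
simulated: Kingman coalescent of the sampled gene copies (pairwise
coalescence rate 1, mutation rate θ/2 per lineage), stepwise ±1 mutations
(SMM) or, with probability 1 − p_smm, multi-step jumps of geometric
magnitude (TPM; defaults p_smm = 0.95 and geometric success probability
0.25, giving jump variance 12 — the conventional settings for this family
of tests, configurable).  θ is tuned by bisection
on the mean simulated allele count (200-replicate pilots, 24 iterations),
then replicates are retained only when k matches exactly.  The simulator
was checked against the Ohta–Kimura closed form E[1 − He] = 1/√(1 + 2θ).

Across loci, standardized differences (He − mean Heq)/sd(Heq) enter a
Wilcoxon signed-rank test (exact distribution at ≤ 25 loci via scipy);
one-tailed excess is the bottleneck signal, and deficit/two-sided
p-values are also reported.  Two practical findings are documented here
because they matter for use: (i) the conditional He distributions must be
estimated with thousands of replicates — with only a few hundred, the
noisy means distort the null and the test loses its size (the calibration
test uses 1,500 per (n, k) and observes type-I ≈ 0.05); (ii) with 8 loci
the exact signed-rank distribution is discrete, so the attainable type-I
at α = 0.05 is ≈ 0.04 even for a perfectly calibrated statistic.

## mtDNA workflow

Haplotype collapsing is strict complete-case by default: sequences with
any non-ACGT symbol are removed before grouping, matching the usual
"sequences with missing data removed" preprocessing; a `keep` policy
exists.  Hd = n/(n−1)(1 − Σpᵢ²) over haplotype frequencies; π is the mean
pairwise difference count divided by alignment length; S counts columns
with ≥ 2 observed states.

K2P distances d = −½ ln((1 − 2P − Q)√(1 − 2Q)) use pairwise deletion of
ambiguous sites; saturated pairs are flagged infinite (and replaced by
10× the largest finite distance when a tree requires finite input).
Neighbour-joining uses scikit-bio; bootstrap support resamples alignment
columns and counts recurrences of each bipartition.  Lineage assignment
joins a query to the lineage of its nearest reference(s) by tree path
distance; path length rather than rooted clade membership defines the
neighbourhood because NJ topology is arbitrary across zero-length branches
(identical haplotypes), which a clade-walking rule misreads.  Ties across
lineages leave the query unassigned with a diagnostic, as do queries with
fewer than 100 unambiguous sites overlapping the references.

The mismatch distribution is fitted to the sudden-expansion model.  In
mutational time (τ = 2ut), a pair coalesces at rate 1/θ₁ until τ and 1/θ₀
before, giving the closed form

F_i = a^−(i+1)/θ₁ · γ̃(i+1, aτ) + e^{τ(1/θ₀−1/θ₁)} b^−(i+1)/θ₀ · Γ̃(i+1, bτ),

a = (θ₁+1)/θ₁, b = (θ₀+1)/θ₀ (regularized incomplete gammas; the ancient
term is evaluated in log space because its prefactor overflows for small
θ₀).  At τ = 0, θ₀ = θ₁ this reduces to the geometric equilibrium curve
θⁱ/(1+θ)^{i+1}.  The fit minimizes SSD by bounded Nelder–Mead from three
starts.  Raggedness is Σ(xᵢ − xᵢ₋₁)² over classes 0..d_max with virtual
zero classes on both ends (a point mass at zero differences gives r = 2);
conventions differ between programs, so this one is pinned here.  p-values
for SSD and raggedness come from a parametric bootstrap: two-epoch
coalescent simulation under the fitted parameters, refitting each
replicate.  Only the demographic (not the spatial) expansion model is
implemented; the spatial variant answers the same qualitative question for
this pipeline's purposes.

## Synthetic generator

The generator emulates a regional wildlife-trade survey: 10 reference
populations of (13, 5, 23, 36, 12, 19, 6, 11, 45, 9) individuals at 20
dinucleotide-ladder loci; two urban markets (84 and 248 animals) and one
10-animal seizure mixing all sources; 18 strictly private alleles injected
across 7 loci and 7 populations at frequency 0.25 by default; 4% duplicate
individuals; 5% missing calls.  Population frequencies are
Dirichlet(c · ancestral) draws with c = 40, chosen because the expected
pairwise differentiation ≈ 1/(1+c) then sits in the weak within-lineage
band (≈ 0.006–0.048) such surveys report; the ancestral spectrum is a
skewed Dirichlet(0.8) over 6 alleles, putting uHe in the 0.6–0.7 range.
Spatial autocorrelation enters through a Gaussian copula on the Gamma
variates behind the Dirichlet draws (exponential kernel over a coordinate
transect, scaled by `ibd_strength`), so marginals stay exactly Dirichlet
while nearby populations covary — enough structure for the Mantel test to
detect isolation by distance with high power.  The heterozygote deficit is
produced by an f-mixture at the genotype level (probability f of an
identical-by-descent homozygote, per-population f in 0.11–0.22): this is
mathematically a Wahlund-style deficit but mechanistically inbreeding-like,
chosen for exact controllability; pooling two demes reproduces the same
signature less controllably.  Null alleles, when requested, silence each
gene copy independently at a chosen rate.

What the generator does **not** emulate: genotyping error beyond null
alleles (no stutter or allelic dropout structure), mutation-model realism
beyond SMM-style ladders, linkage, spatially continuous populations, or
uncertainty in market mixture weights (the defaults are illustrative —
nothing in reference data can constrain true market sourcing).  Passing
tests on synthetic data therefore demonstrate correctness of the
estimators and the tracing logic under the stated model, not robustness to
artefacts absent from it.

## Scales used in tests and the acceptance script

Simulation-based checks are scaled to single-core runs: 10⁶ Monte-Carlo
pairs per identity-index comparison; 200–300 null replicates for each
calibration (Mantel, F_IS randomization, bottleneck excess); a
1,500-replicate Heq bank; 100–1,000 mismatch bootstraps; the bottleneck
stage of the acceptance script runs on a 30-individual reference
subsample.  These sizes were chosen once as the smallest giving stable
verdicts for the properties tested.

## Known limitations

- GenAlEx dialect parsing is strict; regional CSV variants (semicolon
  separators, trailing columns) are rejected rather than guessed.
- The Monte-Carlo null-allele test ignores allele-size classes.
- Pairwise F_ST permutation tests are not corrected for multiple pairs
  (a Bonferroni helper is provided separately).
- `assign_lineage` is distance-based; it does not attempt placement-aware
  (likelihood) assignment and will leave genuinely intermediate sequences
  unassigned.
- The bottleneck θ-tuning targets the mean allele count; for very small
  samples (< ~20 gene copies) the conditional acceptance rate can be low
  and `max_attempts` may truncate the retained sample.
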