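# Methods

## Meiosis and segment tracking

Every founder carries two haplotypes, each a single chromosome-length run
with a unique integer id (ids are assigned per replicate in generation,
founder, haplotype order, so a given pedigree structure always yields the
same id layout). A non-founder haplotype is formed by one meiosis on one
parent: a fair coin selects the starting parental haplotype; crossover
positions are sampled in Morgans on the genetic axis of the parent's sex
(sex-specific models) or on the sex-averaged axis (sex-averaged models);
each genetic position is converted to a physical coordinate by linear
interpolation in the map; the gamete copies parental runs, switching the
source haplotype at every crossover. Run end coordinates stay real-valued
internally and are rounded to integer bp only when written to disk, which
keeps repeated coordinate conversions exact. A crossover that lands
exactly on an existing run boundary keeps the left run's identity, so no
zero-length run is ever created (tested).

Pairwise IBD is computed by sweeping the merged run boundaries of the four
haplotypes and classifying each interval by maximal bipartite matching of
founder ids: two disjoint matches give IBD2, one gives IBD1. The maximal
matching (rather than a simple count of equal pairs) handles inbred
configurations in which three haplotypes share one id. Adjacent intervals
of equal type are merged; segment genetic coordinates are always reported
on the sex-averaged axis, and the sharing fractions k1/k2 are sex-averaged
genetic lengths divided by the total map length. IBD proportion is
k2 + k1/2 and kinship k2/2 + k1/4; kinship maps to a degree of relatedness
through the standard powers-of-two ranges (degree d for kinship in
(2^−(d+1.5), 2^−(d+0.5)]).

## Crossover models

Under the Poisson model, inter-crossover distances are Exponential(1) per
Morgan. Under the two-pathway interference model, a fraction p of
crossovers escape regulation (Poisson, rate p/Morgan) while chiasmata of
the regulated pathway form a stationary gamma(ν, 2ν(1−p)) renewal process
thinned by independent fair coins (no chromatid interference). The
stationary start is realized by beginning the renewal a burn-in distance
B = max(10, 5/(2ν(1−p))) Morgans before the chromosome: renewal processes
forget their origin geometrically, and at human-like parameters B = 10
Morgans is ≈19 mean inter-chiasma distances, so the residual
non-stationarity is far below Monte-Carlo resolution (the suite tests
equality of event counts in early and late windows). This avoids numeric
inversion of the equilibrium first-interval distribution.

Sex-averaged interference parameters combine the per-sex estimates as
p_a = (p_f + p_m)/2 and ν_a = (1/(2ν_f) + 1/(2ν_m))^−1; the ν rule makes
the variance of the sex-averaged inter-chiasma distribution the mean of
the two sexes' variances (every ν gives the same mean, 1/(2(1−p))).

**Defaults.** The package ships genome-wide defaults ν_f = 5.0,
p_f = 0.06, ν_m = 7.0, p_m = 0.04 — the regime of published human
family-data fits of the two-pathway model (gamma shape ≈4–8, escape
fraction ≈2–10%, females with weaker interference and a larger escape
fraction). The interference-parameter file format also accepts
per-chromosome values, with `*` as the genome-wide fallback, since
published estimates exist in both granularities.

## Sampling and reproducibility

All randomness flows from one seeded numpy Generator. Replicates are
simulated in chunks; within a chunk, crossovers for one (meiosis slot,
chromosome) are drawn in a batch per parent sex, in a fixed order (couple
sex coins, then per slot: start coins, free-process events, regulated
chiasmata, thinning coins), so output is bit-reproducible given the seed.
The batch Poisson sampler uses the count + sorted-uniform construction
(identical in law to sequential exponentials, which the scalar API keeps).

## Synthetic genomes

Three packaged fixtures stand in for real resources so every test runs
offline:

* **single chromosome** — one linear 2.8-Morgan chromosome (no sex
  dimorphism) for segment-length theory comparisons;
* **desk genome** — 8 chromosomes, 90 cM male / 141.3 cM female each,
  with gamma-weighted knot increments (roughness 0.4) for fast
  model-contrast experiments;
* **human-scale genome** — 22 chromosomes, male lengths 190→55 cM
  (total ≈2700 cM), female 1.57× longer (≈4230 cM), physical lengths
  250→50 Mb, mirroring the autosomal totals of pedigree-based human maps.

The generator reproduces the genome-wide female:male dimorphism and
moderate local rate variation (independent gamma increments per sex), but
*not* the strong, spatially organized male/female rate structure of real
maps (male recombination concentrated near telomeres, female near
centromeres, per-chromosome dimorphism varying from ~1.2× to >2×).
Consequences measured with this package: statistics driven by total
genetic lengths reproduce published values closely (maternal:paternal
half-sibling segment-count ratio ≈1.40; sixth-cousin non-zero-sharing
rates ≈9–13% by lineage sex; interference's ≈10% reduction of SD(IBD
proportion)), whereas the sex-specific-map *increase* in SD(IBD
proportion) — which feeds on local rate structure — is attenuated to
≈+1% here versus ≈+4% reported with real maps. Passing tests therefore
demonstrate the mechanisms and their directions, not the exact magnitude
of map-structure-dependent effects in real human data; the pipeline can
be pointed at converted real map/interference files (see README,
"Reproducing the results") for the quantitative comparison.

## Segment-length theory

The closed forms use β = 2(1−p)ν and series over the number of skipped
chiasmata, truncated at k_max = 50 (the neglected geometric mass is
2^−50; the suite checks k_max 50→100 changes nothing above 1e−10).
Incomplete-gamma terms use the regularized functions to avoid overflow at
large kν. The upper tail G̃(x) is evaluated term-wise as
(kν/β)Q(kν+1, βx) − x·Q(kν, βx) (Q the regularized upper incomplete
gamma), which avoids the catastrophic cancellation of 1 − G(x) in the
tail. φ is evaluated in the expanded form that never divides by G̃, so it
stays finite where G̃ underflows.

The finite-chromosome density uses ∫ₓ^∞ φ = h(x)/(2T) (a consequence of
φ = −h′/(2T)), giving φ_L(x) = [2h(x)/(2T) + (L−x)φ(x)] / (L + 1/(2T))
with an explicit atom at x = L of mass (∫_L^∞ h/(2T)) / (L + 1/(2T)); the
atom is returned separately from the continuous part so total mass is
directly testable. The only numerical integration is the atom's tail
integral (adaptive quadrature over 30/(2T) Morgans past L; the integrand
decays exponentially).

The sex-specific Poisson density discretizes the male/female per-bp rates
on a regular grid (default 10 kb), evaluates the inhomogeneous-Poisson
inter-event density by sums over that grid, and mixes over the number of
female transmissions n_f = n_f,i + 2·n_f,a with n_f,i ~ Binomial(2T−2, ½)
and n_f,a ~ Bernoulli(½) (the transmitting common ancestor's sex counts
twice because that ancestor performs two of the 2T meioses).

Simulated IBD segment lengths are compared to φ_L by chi-square with
equal-probability bins (the atom folded into the last bin). IBD segments
are a randomly selected subset of the inter-crossover partition of the 2T
path meioses, so their length law follows φ_L only approximately; at the
sample sizes used (10^5 pairs for T = 1, 2; 5×10^4 for T = 4, 6, one
2.8-Morgan chromosome) the approximation is within Monte-Carlo noise
(goodness-of-fit not rejected at α = 0.01).

## Genotype synthesis

Founders of each replicate are injectively assigned samples from a phased
input VCF; descendant alleles are copied from the assigned founder
haplotypes through the tracked segments (pysam handles VCF I/O; gzipped
files work). Per site and individual, independently: with probability
err_rate an error is applied (biallelic sites only — multi-allelic sites
are copied through unchanged): heterozygous → either homozygote with
equal probability; homozygous → heterozygous, except with probability
err_hom_to_opposite → the opposite homozygote. With probability miss_rate
the genotype is set missing, after and overriding any error. Defaults:
err_rate = miss_rate = 1e−3, err_hom_to_opposite = 0. Sites outside the
mapped span are dropped and counted.

## Admixture dating

The admixed pedigree places the admixture event T generations back with
every founding couple mixing the two populations. Generation-1 ancestors
are unadmixed, so their meioses cannot move an ancestry breakpoint; the
simulator therefore starts from their generation-2 children (one
whole-genome population-A haplotype, one population-B), which is exactly
equivalent for local-ancestry output and halves the meiosis count. The
focal individual's single admixed haplotype is extracted, same-population
neighbors merged, and lengths measured in sex-averaged Morgans.

Censoring: only the segment running into the chromosome end is censored.
The per-chromosome likelihood is then (T/2)^k e^(−TL/2) for k interior
switches — the exact Poisson-process likelihood — and the MLE
T_hat = 2(n−m)/Σx_i is unbiased (the denominator is the fixed genome
length). Flagging the first segment as censored too would drop one
exponential observation per chromosome and bias T_hat low by roughly
2·(#chromosomes with a switch)/genome-length; the package's suite checks
unbiasedness directly. A single whole-chromosome segment is censored and
counts once in m; if every segment is censored the estimate degenerates
to 0 and is flagged.

## Experiment drivers and statistics

Quartiles use linear interpolation between closest ranks (numpy's
default, "type 7"). SDs use the n−1 denominator. Bootstrap standard
errors resample pairs with replacement (default B = 1000; B = 100–200 in
the heavier test cells, where bootstrap noise is negligible relative to
the effects tested). The separation between two datasets is reported as
D = |θ_model − θ_real| / sqrt(SE_model² + SE_real²).

Problem sizes in the shipped tests and acceptance script (chosen for a
single-CPU workflow; all scale linearly): 10^4 pairs per cell for the
model-contrast grid (full siblings through second cousins × four models);
2–4×10^3 pairs for sharing means, half-sibling counts and sixth-cousin
rates; 2–2.5×10^3 replicates per cell for admixture dating; 3×10^4–10^5
pairs for segment-length comparisons. The published study used 10^4 pairs
per relatives cell, 1.5×10^4 admixture replicates and up to 10^6 pairs
for segment-length histograms.

## Known limitations

* No sex chromosomes; no crossover-count correlations across chromosomes
  ("gamete effects"); no χ²-model compatibility mode.
* The def-file dialect covers the symmetric branch structures described
  above; asymmetric structures are covered by the relationship presets
  (half-siblings, half/removed cousins, forced-lineage-sex cousins).
* Interference theory is derived for the sex-averaged map only, and the
  sex-specific closed form assumes Poisson placement (both as in the
  underlying derivations); the simulator itself supports all four
  combinations.
* The synthetic map generator under-represents the local structure of
  real sex-specific maps (see "Synthetic genomes" above).
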