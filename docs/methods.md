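# Methods

`tamemap` re-implements, as a reusable pipeline, the selection-mapping
analysis of a wild-derived heterogeneous stock (WHS) of mice: a stock founded
from eight wild-derived inbred strains spanning three *Mus musculus*
subspecies and bred for twelve generations, with within-family truncation
selection on "contacting" (seconds spent in contact with a human hand) in
the selected lines.  This note describes the models, the choices made where
the design was genuinely open, and what the synthetic data do and do not
establish.

## Founder panel and allele-sharing classes

Founders are treated as fully inbred and homozygous, so each strain
contributes one allele call per SNP.  QC follows the array-panel rules:
biallelic, polymorphic among the eight founders, autosomal (chromosomes
1–19; X and Y excluded), and a missing-call fraction below 1% computed over
the founder calls plus any attached sample genotypes (a founders-only mode
is available, since it is ambiguous which denominator the original QC
used).  SNPs with more than two observed alleles are dropped with a logged
count rather than an error.

Each SNP's *sharing category* is the size of the smaller allele-carrier
partition, `min(k, S - k)` for carrier count `k` among `S = 8` strains
(1–4).  Category-1 ("private") SNPs are perfect ancestry markers for their
carrier strain: given inbred founders, the private-allele frequency in any
sample equals that strain's founder-ancestry frequency at the position.
The published GigaMUGA tallies for this stock (20,530 / 19,719 / 9,167 /
2,719 SNPs in categories 1–4; per-strain private counts from 8,109 for
PGN2 down to 108 for KJR) are stored as reference constants.

## Breeding design

The WHS mating plan is generated as: G0, eight circular-rotation pairs
(female of strain *i* × male of strain *i−1*); G1, rotation again with an
offset of two families; G2, expansion from 8 to 16 pairs by taking two
daughters and two sons per G1 family; G3 onward, random pairing that avoids
full-sib matings (a permutation over families with no fixed point, found by
rejection with a retry cap), one female and one male breeder per pair.
Cousin matings are allowed — the realized rule only barred sib crosses.
When phenotypic selection is simulated, each pair instead produces five
candidates per sex and a selection hook picks the breeder (top contacting,
ties broken by higher heading, then at random; control lines pick uniformly
at random).  Group splits follow the realized four-line plan (S1/C1 from
G3; S2 split from C1 and C2 from S1 at G5) or a simplified two-line plan,
which is the default for desk-scale work.

## Gene dropping

Crossovers follow a Poisson process along the genetic map (Haldane model:
no interference, no obligate chiasma; the count per chromosome is
Poisson(L/100), breakpoints uniform, starting haplotype a fair coin).  The
19 autosomes are inherited independently; sex chromosomes, mitochondria,
mutation, and genotyping error are not modeled.

Two engines implement the same process:

* a **segment-mosaic engine** (`simulate_meiosis` / `gene_drop`) that
  tracks full founder-labelled haplotype mosaics (half-open cM segments
  tiling each chromosome), used wherever whole genomes are needed;
* a **marker-resolution engine** (`ancestry_gene_drop`) that simulates
  founder ancestry only at marker positions.  Along a chromosome the
  copied-haplotype indicator is a two-state Markov chain whose switch
  probability between markers d cM apart is the Haldane map function
  `(1 − e^(−2d/100))/2`; across a chromosome boundary the switch
  probability is exactly 1/2, which is an independently re-tossed starting
  haplotype, so all chromosomes are simulated on one concatenated marker
  axis.  This is exact at the markers — not an approximation — and is what
  makes 10,000-replicate null distributions affordable.  The two engines
  are cross-checked against each other in the test suite.

## Selection mapping

For each founder strain, one null simulation performs a no-selection gene
drop through the fixed pedigree and records the **maximum** over that
strain's private SNPs of the strain-ancestry frequency among the
final-generation breeders (default: the 32 breeders of generation 12).
Repeating this (default 10,000 times) gives a per-strain null distribution
of genome-wide maxima; maxima are per strain, not pooled, because the
published per-strain thresholds differ with private-marker density.

The genome-wide threshold at level α with Bonferroni correction over `m`
tests (default `m = 16`: eight strains × two selected groups) is the
smallest simulated value `t` with `#{maxima ≥ t}/N ≤ α/m`.  The maxima are
discrete — multiples of 1/64 for a 32-mouse sample — so this tie-aware rule
is deliberately conservative: the attained level (exposed as
`attained_level`) is at or below the nominal one, never above.  A
degenerate null in which no value reaches the target tail falls back to
the largest simulated value with a warning.  Empirical p-values are plug-in
tail fractions `#{maxima ≥ observed}/N` with no +1 correction (consistent
with a reported p of 17/10,000 at N = 10,000); zero is formatted as
"< 1/N".  Observed frequencies at or equal to the threshold count as
significant, and runs of consecutive significant private SNPs are merged
into candidate regions.

## Heterozygosity windows

Observed heterozygosity per SNP is the fraction of heterozygous calls among
non-missing individuals.  Windows of 100 consecutive SNPs advanced by 10
SNPs are computed within chromosomes only (windows never span a boundary;
trailing SNPs not covered by a full window are ignored), and windows whose
mean is at or below the genome-wide empirical 10th percentile are flagged
(ties included, so a perfectly uniform track flags everything).
Overlapping or abutting flagged windows are merged into candidate
intervals; both the raw windows and the merged intervals are reported, the
latter also as 0-based half-open BED.

## Response, differentials, realized heritability

Response per generation is `G_t` = selected-line mean − contemporaneous
control-line mean.  The within-family selection differential for one
(family, sex) cell is the selected animal's trait value minus the mean of
all same-sex candidates in that family; cells are averaged within the line
per generation and cumulated.  (The literal "selected parents minus their
offspring" variant is available as `method="parent-offspring"`.)

Realized heritability is the slope of the through-origin regression of
cumulative response `R(t) = G_t − G_{t0}` on the cumulative differential,
lagged one generation (selection at generation t acts on t+1); zero
cumulative differential implies zero expected response, and an
intercept-including fit is reported as a diagnostic.  The default standard
error is the OLS slope SE; the ratio variant (sampling variance of the
responses over the final cumulative differential) sits behind a flag, as
the published SEs are not reproducible from first principles.

A note on what within-family selection estimates: with candidates sharing
both parents, only the segregation variance Va/2 and the residual Ve vary
within a family, so the regression recovers `h²_w = (Va/2)/(Va/2 + Ve)` —
the *within-family* realized heritability — not the narrow-sense
`Va/(Va+Ve)`.  The polygenic calibration generator is therefore
parameterized directly by the realized value (`realized_h2`), solving for
Va at fixed phenotypic variance; conveniently, Va/2 + Ve is constant under
the infinitesimal model, so the planted slope does not drift as selection
proceeds.

## Allele retention (design evaluation)

Each replicate drops one unlinked locus with eight distinct founder alleles
through an independent realization of the mating design and asks which
alleles survive among the final-generation breeders (the animals that would
found the next generation).  The pedigree is resampled per replicate —
design evaluation precedes any realized pedigree.  The design scheme is the
WHS plan itself; a constant-pair-count random-union scheme is included for
comparisons at other sizes.  At 16 pairs and 12 generations roughly 60% of
replicates lose at least one allele and none reach fixation; at 8 pairs the
loss fraction is ≈98%, matching the prior-literature figure for a
half-sized stock.

## Synteny overlap permutation test

Genes overlapping a query region are projected through a one-to-one
orthologue subset (first mapping per gene) into the second genome, and the
count k of distinct sweep segments overlapping any projected interval is
recorded.  The null places regions of the same length uniformly over all
genome-A start positions admitting a full-length placement, pooled across
chromosomes (probability proportional to admissible length; placement is
not restricted to gene-bearing territory — an open choice, documented);
P = `#{samples with k ≥ k_obs}/n`.  All interval logic is 0-based
half-open.

## Synthetic data: what it emulates, and what it does not

The panel generator places SNPs uniformly on a discrete cM grid over 19
equal autosomes (default 70 cM each, ≈1,330 cM total, 2 Mb/cM) with
category counts defaulting to the published tallies divided by ten
(5,214 SNPs) and category-1 carriers drawn proportionally to the published
per-strain private counts, so per-strain marker densities — and hence
threshold spreads — are realistic.  The phenotype model is a single
additive QTL on one founder's haplotype (default: effect 1.5 s per copy on
chromosome 11, carried by MSM) plus a family effect (σ_f = 0.5 s), a
residual (σ_e = 2.0 s), a baseline of 1.0 s, heading correlated at ρ = 0.6,
and flooring at zero, which reproduces the zero-inflation of unselected
lines.  A second linked QTL on the same haplotype (configurable cM offset)
can emulate a two-locus architecture.  These defaults are desk-scale
choices made once for adequate statistical power at 16 pairs; they are not
estimates of the real stock's genetics, and nothing constrains the real
effect sizes.

What passing tests therefore show: that the pipeline is internally
calibrated (null false-positive rates at or below nominal), recovers
planted signals of the modeled kind, and matches analytic and enumerative
oracles.  What they do not show: robustness to genotyping error, array
ascertainment bias, residual founder heterozygosity, crossover
interference, epistasis, or the realized pedigree's deviations from the
design (failed pairs and substitutions), none of which are modeled.

## Problem sizes and numerical choices

Default test-suite scales, chosen as desk-scale renditions of the study
conditions: panels of 5,214 SNPs; 2,000-replicate null distributions for
threshold work (10,000 remains the library default); 10,000-replicate
retention runs; 1,000 drops for the equal-contribution check; 50 seeds for
power; 20 replicates per heritability recovery point.  Random-number use is
explicit everywhere: every stochastic function takes a seed or Generator,
dataset generation splits one SeedSequence into independent streams for
panel, pairing, and biology, and identical configuration plus seed gives
byte-identical outputs.  Degenerate inputs (zero-length chromosomes, empty
categories, strains without private SNPs, all-missing SNPs, chromosomes
shorter than one window) follow the documented warning/error behavior
rather than silent coercion.
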