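# Methods

## The study system and what the package computes

PEDS (percentage of cupules bearing a single spikelet) separates the
teosinte ear (PEDS = 100%) from the maize ear (PEDS = 0%).  In advanced
maize × teosinte backcross populations bred by recurrent selection of
PEDS = 100% plants, the trait is zero-inflated — roughly one plant in
sixteen shows any single spikelets — and its genetic architecture
combines one major QTL, minor QTL and strong additive-by-additive
epistasis.  `pedsmap` implements the two analysis arms used on such
populations (bulked-segregant QTL-seq and interval mapping on a local
linkage map) and a forward simulator that supplies populations with a
planted architecture, so every stage can be validated by recovery of
known truth.

## Forward simulator

**Genomes and meiosis.**  Each chromosome copy is a mosaic of
founder-labelled segments (maize / teosinte) on the genetic axis.
Meiosis draws a Poisson number of crossovers with mean equal to the map
length in Morgans and uniform positions — a no-interference (Haldane)
process.  The map-estimation arm deliberately uses the Kosambi function
instead (see below); this simulation/estimation mismatch is
intentional: it mirrors the usual practice of mapping with Kosambi
distances whatever the true interference, and it is why estimated local
maps are slightly compressed relative to simulated truth.  The Kosambi
estimator itself is tested against two-point data generated from its
own model.

**Breeding scheme.**  F1 → F2; plants with PEDS = 100% (exactly; if
none exist the simulator raises an error rather than silently relaxing
the rule) are backcrossed to the maize parent; each BCnF1 is selfed;
selection repeats until BC3F2 or BC4F2.  Default generation sizes are
2,000 plants per intermediate F2-type generation and 8,000 in the final
mapping population, matching the scale of the field evaluations the
system emulates (4,320–7,990 plants per environment).

**Phenotype link.**  A latent score
`G = mu + sum_j (a_j x_j + d_j z_j) + sum_kl aa_kl x_k x_l + e`,
`e ~ N(0, sigma_e^2)`, with x = +1/0/−1 for maize-homozygote /
heterozygote / teosinte-homozygote and z the heterozygote indicator, is
censored to [0, 1] and scaled: `PEDS = 100·clip(G, 0, 1)`.  The
censored-linear ("tobit-like") link is the simplest mechanism that
produces both the observed point mass at 0 and the long right tail; a
logistic link would need extra shape parameters to do the same.
Negative `a` means the teosinte allele increases PEDS, matching the
sign convention of Add in the linkage arm.

**Default architecture** (`default_config`): a major QTL on
chromosome 3 at 43 Mb (a = −0.50, d = −0.40), strong modifiers on
chromosomes 1 (a = −0.50, d = −0.45) and 8 (a = −0.25, d = −0.20), a
minor QTL on chromosome 6 (a = −0.12, d = −0.09), one
additive-by-additive pair between the chromosome-3 and chromosome-8
loci (aa = +0.35), mu = −0.58, sigma_e = 0.10.  These values were
calibrated once, by enumeration over the 1:2:1 genotype classes plus
simulation, to reproduce three field observations simultaneously: (i)
the fraction of BC3F2 plants with PEDS > 0 lies in the observed
1/17.5–1/14.8 band (simulated ≈ 1/15–1/17); (ii) PEDS > 90% plants
occur at ~1%, enough to draw 50-plant high bulks from an 8,000-plant
population; and (iii) PEDS = 100% plants exist at a few per thousand,
so the recurrent-selection rule remains satisfiable in every
generation.  The effectively recessive major locus and the strong
interaction also reproduce the qualitative finding that single-locus
near-isogenic material rarely expresses the trait.

**Single-QTL configuration** (`single_qtl_config`): one QTL
(a = −0.30, d = −0.10, mu = 0.25, sigma_e = 0.26) calibrated once by
Monte-Carlo variance decomposition at n = 200,000 so that the locus
explains 35% of the variance of cube-root PEDS in an F2-type
population — the scale of the major QTL's reported PVE (33.91–38.05%).
It drives the planted-truth recovery studies.

**Bulk sequencing.**  Only read counts are simulated.  Every
diagnostic SNP is parent-diagnostic with the maize allele as REF and
the teosinte allele as ALT (this fixes the orientation of "alternate
base" once and for all).  Per bulk and SNP: the true teosinte-allele
frequency p is the dosage mean over bulk members, depth D ~
Poisson(lambda = 19, the bulks' reported mean depth), alternate count ~
Binomial(D, p(1−eps) + (1−p)eps) with eps = 0.001.  Diagnostic-SNP
density defaults to one per 100 kb — dense enough that 1 Mb windows
hold ~10 SNPs, a desk-scale stand-in for the millions of SNPs of real
resequencing.

**What the simulator does not emulate:** sequence-level reads (no
FASTQ, no alignment or base-quality structure), genotyping error in
marker calls, missing data, photoperiod × genotype interaction (the
day-length collapse of the trait in one environment is out of scope),
and varying family structure within generations.  Passing recovery
tests therefore show that the statistics recover truth under clean
Mendelian sampling and Poisson-binomial counting noise — not that they
are robust to alignment artifacts or phenotyping error.

## QTL-seq arm

SNP-index = alt/(ref+alt) per bulk; sites with depth < 4 or > 32 in a
bulk are masked there (4 and 32 themselves pass); Δ = high − low where
both pass.  Windows of 1 Mb advance in 10 kb steps, anchored at
position 0 of each chromosome, half-open on the right, with membership
`start ≤ POS < end`; a window needs ≥ 3 passing SNPs (guard against
sparse-window artifacts), otherwise its mean is missing.  Multi-allelic
sites are dropped with a logged count.

The null band follows the simulation logic of the original QTL-seq
proposal: per replicate and bulk, n individual dosages are drawn (F2
design 1:2:1 by default; a backcross design 1:1 is selectable — the
true genotype distribution inside selected advanced-population bulks is
not derivable from first principles, and the F2 choice is the single
largest modelling judgement call here), p = mean dosage / 2, depth ~
Poisson truncated to the filter pass band, alt ~ Binomial(D, p).  The
2.5/97.5 and 0.5/99.5 percentiles over 10,000 replicates per tabulated
depth give the 95% and 99% bands.  Because raw Monte-Carlo quantiles
are not exactly monotone across depth, a running envelope (running
minimum of upper quantiles and maximum of lower quantiles with
increasing depth) enforces the physically expected narrowing; at
10,000 replicates the adjustment is within quantile noise.  A window is
significant when its mean Δ strictly exceeds the band at the nearest
tabulated depth (ties count as non-significant); runs of consecutive
significant windows merge into candidate regions, and because
overlapping windows can split one signal across runs separated by a
single sub-threshold window, bp-overlapping regions are further unioned.
No multiple-testing correction beyond the simulated genome-wide band is
applied, matching the source method.

## Linkage arm

**Marker QC.**  χ² against 1:2:1 (2 df).  In a selected advanced
population nearly every marker is legitimately distorted, so the screen
is run on an unselected F2 sample of the same cross (200 plants in the
pipeline), as in the original protocol where markers were screened on
36 F2 plants before genotyping the mapping populations.  The pipeline
applies a Bonferroni-corrected threshold (0.05 / number of markers):
"serious" distortion — selection or scoring failure, with p-values
many orders of magnitude below any threshold — is still caught, while
chance failures of linked marker blocks (which would punch holes in the
map around the very QTL under study) are avoided.  The uncorrected
α = 0.05 default of `build_local_map` is kept for direct use.

**Two-point estimation.**  The recombination fraction maximises the
multinomial likelihood of the nine joint codominant genotype classes
(the double-heterozygote class automatically mixes the two phases) by
bounded scalar search on [0, 0.5]; LOD = log10 L(r̂) − log10 L(0.5).
Marker order is fixed by physical position — the study's markers are
physically anchored and de-novo ordering is out of scope — and
adjacent r̂ are converted by Kosambi (cM = 25·ln((1+2r)/(1−2r))) and
accumulated from 0 per chromosome.  Missing genotypes are excluded
pairwise, never imputed.

**ICIM scans.**  Phenotypes are cube-root transformed (the standard
skewness reduction for this trait; 0 maps to 0, 100 to 100^(1/3) ≈
4.64).  Phase one selects background cofactors by forward–backward
stepwise least squares over per-marker (x, z) blocks with partial-F
probability thresholds p_in = 0.01 / p_out = 0.02 (suitable for small
local maps; configurable), deterministic with ties broken by
(chromosome, bp).  Cofactors are restricted to markers on the map: an
off-map marker adjacent to a QTL would otherwise absorb its effect
during background adjustment.  Phase two walks a 1 cM grid; at each
position the phenotype minus all cofactor effects except the flanking
markers' is regressed on the expected QTL scores E[x*] = P(QQ) − P(qq)
and E[z*] = P(Qq), computed from the flanking genotypes by exact
three-locus enumeration under no interference (missing flanks
marginalised; both missing gives the 1:2:1 prior).  LOD =
(n/2)·log10(RSS0/RSS1); PVE = 100·(RSS0 − RSS1)/TSS of the adjusted
phenotype; Add and Dom are the fitted coefficients.  This Haley–Knott
regression approximation to the mixture likelihood is adopted instead
of re-deriving the exact ECM internals of the reference software; at
the heritabilities involved its bias is negligible relative to sampling
error (the recovery study estimates mean PVE ≈ 35 for a planted 35%
QTL).  Peaks are maxima of contiguous runs with LOD ≥ 3 (the usual
declaration threshold; no permutation thresholds, matching the source
analysis).

The two-locus scan uses a 5 cM grid (the granularity at which epistatic
positions are conventionally reported) and, for each pair at least one
step apart, compares the full digenic model (main a/d terms of both
loci plus aa, ad, da, dd products of expected scores) against the
main-terms-only model; LOD ≥ 5 retains a pair, AA is the fitted aa
coefficient (positive = parental allele combinations increase the
trait), and the pair's PVE is the interaction block's incremental R²
× 100 (the reference decomposition is not specified; this choice is
documented, not inferred).  Retained pairs are thinned to local LOD
maxima over neighbouring grid pairs.  Whether the reference LOD
compares against a no-epistasis or a null model is unstated there; the
main-terms-only comparison isolates the interaction, which is what the
AA column reports.

## Pipeline and reproducibility

`run_all` executes simulate → summarize → bulks → counts → thresholds →
snp-index → call-regions → build-map → scan-qtl → scan-epi → recovery,
writing every intermediate table, per-stage logs with filter counts,
and a manifest with content hashes.  Every stage draws from its own
substream `default_rng([seed, stage_id])` with fixed stage identifiers,
so adding a stage cannot shift another stage's randomness; identical
config + seed gives byte-identical outputs.  Tables use 1-based bp
positions; BED exports are 0-based half-open.

## Problem sizes of the validation studies

The replicated studies use sizes chosen for desk-scale runs while
keeping every estimate stable: QTL-seq recovery 12–20 replicates of a
full scheme ending in 3,000 plants with 50-plant bulks; interval-
mapping recovery 12–40 replicates at n = 650 (the BC4F2 scale);
epistasis recovery 10 replicates of an F2 with 650 plants; null-band
calibration 10,000 replicates per depth and 10,000 fresh test SNPs.
Across these, region recovery and peak recovery are at or near 100%,
mean recovered PVE is within a point of the planted 35%, and the
realized type-I error of the 95% band is 0.048–0.056.

## Known limitations

* The regression approximation understates LOD slightly relative to a
  full mixture EM at high heritability; effect signs and positions are
  unaffected.
* Candidate regions inherit the autocorrelation of overlapping
  windows: their count is not a calibrated family-wise error quantity,
  and under a pure null the expected number of falsely called regions
  is reported by the null studies rather than bounded analytically.
* The F2-design null band is a modelling choice for selected
  advanced-population bulks; the BC design is available but neither is
  exact for bulks drawn after repeated selection.
* Estimated local maps are compressed relative to simulated truth by
  the Kosambi/Haldane mismatch; comparisons against truth therefore
  interpolate the truth position onto the estimated map.
* PEDS is simulated per plant, not per cupule; within-ear counting
  noise is folded into sigma_e.
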