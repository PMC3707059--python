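# Methods

This note documents the models behind `gbspanel`, the conventions adopted
where a published description leaves room, and what the synthetic-data
validation does and does not demonstrate.

## Canonical data model

A panel is a dense samples × sites array of diploid calls in four states:
homozygous for the first (REF-like) allele, heterozygous, homozygous for
the second allele, missing. The integer code of a non-missing call equals
the dosage of the second allele. Positions are 1-based; sites of a
chromosome are contiguous and position-sorted; equal positions occur only
when a multi-allelic VCF record has been split (opt-in) and then must
differ in allele pair. Allele order is as read; frequencies and dosages are
derived per analysis, never stored.

All diversity statistics first *haploidize*: heterozygous calls become
missing, treating each inbred as a random draw of one haplotype from its
population. Residual heterozygosity in inbred lines is real but sparse, so
the information loss is small, and haploid statistics are insensitive to
the panel's departure from Hardy–Weinberg genotype proportions.

## Synthetic panels (ground truth for every stage)

**Population structure — Balding–Nichols.** Ancestral frequencies are
uniform on [0.1, 0.9] (bounded away from 0/1 so desk-scale panels stay
polymorphic). Each group's frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with
drift parameter F equal to the target fixation index, chosen for its
closed-form link to the Weir–Cockerham expectation: the multi-locus
estimator should recover F. F = 0 short-circuits to the ancestral
frequency. Lines are homozygous draws, then a configurable fraction of
calls becomes heterozygous (residual heterozygosity, placed uniformly at
random — its true genomic distribution is not modeled) and a configurable
fraction of calls is perturbed (base-call error, default 0.2%, replacing
the call with one of the other two states uniformly).

**Pedigrees.** Meiosis places a Poisson number of crossovers per
chromosome (default 2) uniformly along the physical map — a uniform
genetic map, not a real recombination map. Backcross derivation tracks
ancestry per site through b backcrosses to the recurrent parent and then
selfing; the expected recurrent-parent fraction is 1 − (1/2)^(b+1)
(0.96875, "97%", for b = 4), and the realized fraction is measured at
sites where the parents differ. Biparental families are F1s selfed by
single-seed descent (default 5 generations).

**Missingness.** Per-sample call rates are uniform on [low, high]
(default 2–75%, the per-sample coverage range such panels exhibit; the
masking tests use 35%, the average). An optional `genotype_bias`
multiplier lowers a sample's rate in proportion to its genotypic distance
from a designated reference lineage, mimicking reference-alignment bias;
realized rates are clipped back into [low, high]. Masking hides uniformly
chosen observed calls per sample and records every hidden cell, so
restoring the record reproduces the input bit-exactly and imputation can
be scored cell by cell.

**Block constructions.** For haplotype-length calibration,
`simulate_block_pair` builds two lines that differ only at *double*
adjacent-site boundaries every L sites: the double mismatch defeats the
sampler's one-mismatch forgiveness, so sampled lengths concentrate at
L − 2 matching sites and the construction has a known target.
`simulate_mosaic_panel` builds founder-haplotype mosaics with a
configurable low-recombination (longer-block) region, giving qualitative
targets for LD decay and the pericentromere effect (longer haplotypes,
higher LD where recombination is suppressed).

**What the generator does not emulate:** real allele-frequency spectra
(no coalescent demography), linkage between drift and physical position,
read-level GBS artifacts, presence/absence variation as a biological
source of missingness, or pedigree-correlated errors. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under their own assumptions, not robustness to every property
of real GBS data.

## Filtering conventions

- All thresholds are inclusive (≥ at each stated boundary).
- Coefficient of panmixia 1 − H_O/H_E uses H_E = 2p(1−p) with p among
  non-missing calls (a het contributes one copy of each allele).
  Monomorphic sites are defined to have panmixia 1 — the fixation limit of
  complete inbreeding — avoiding 0/0. Discovery defaults: call rate ≥ 10%,
  panmixia ≥ 0.8, MAF ≥ 0.2%.
- Biparental error correction: within-family MAF is computed on
  haploidized calls; a family segregates at a site iff its MAF ≥ 0.15
  (inclusive). The site's apparent error is the **maximum** within-family
  MAF over non-segregating families (conservative; a mean aggregation
  would dilute a single bad family). Families with fewer than 10 genotyped
  members at the site are skipped — too few haploid draws to classify
  segregation. Sites assessable in no family pass vacuously.
- Local-LD test: for each segregating family, r² (squared Pearson on
  haploidized dosage, pairwise-complete members) between the focal SNP and
  a window of the nearest one-twentieth of the chromosome's SNPs by index
  (centered, focal excluded, ties to the smaller index, truncated windows
  extended at chromosome edges), minus SNPs within 100 kb of the focal
  position; median within family, then median across families, pass iff
  ≥ 0.5. Chromosomes with < 20 SNPs use all sites minus the exclusion
  zone. Sites segregating in no family skip the test (flag to invert).

## Imputation conventions

Windows are consecutive 1,024-site index blocks that never cross a
chromosome boundary (the final block per chromosome may be shorter). The
donor minimizing the mismatch fraction over jointly non-missing
haploidized calls fills the target's missing cells if that fraction is
≤ 5%; the donor's own missing cells stay missing, and observed target
calls are never touched. Mismatch is computed on intersections only.
`min_overlap` (default 32 jointly called sites) guards against spurious
zero-mismatch matches on tiny overlaps; at 35% call rate a 1,024-site
window yields ≈ 125 shared calls, comfortably above it, but smaller
windows need a proportionally smaller threshold. Ties break by larger
overlap, then lexicographic donor id, making runs reproducible. An
optional non-haploidized mode scores het-vs-hom comparisons as half a
mismatch. The donor search is restricted to the supplied panel (or an
explicit donor list); accuracy rises with the density of close relatives,
which the veto makes explicit: lines without a sufficiently similar donor
are left missing rather than imputed badly.

## Relatedness conventions

- IBS counts allele sharing per jointly called site (1 same genotype, 0.5
  one shared allele, 0 opposite homozygotes) — PLINK "distance"
  semantics, nearly equivalent to haploid matching on inbred panels.
  Pairs with zero joint sites are NaN and must be resolved before
  ordination.
- LD pruning is greedy indep-pairwise: within each 100-SNP window any
  surviving pair with r² > 0.2 loses its later member; the window slides
  by 25 SNPs per chromosome. The surviving set is verified
  pair-exhaustively in tests.
- IBD (π̂) is a method-of-moments estimate from IBS-class counts and
  sample allele frequencies on the pruned set. The default expectations
  treat lines as doubled haploids: a non-IBD pair shows opposite
  homozygotes with per-site probability 2pq, so π̂ = 1 − IBS0/Σ2pq. The
  classic outbred (HWE) expectations are available as `model="outbred"`
  but are biased on fully homozygous material — IBS1 never occurs there,
  and a simulated four-backcross pair estimates ≈ 0.89 instead of the
  pedigree expectation 0.96875, which the doubled-haploid form recovers.
  Raw estimates are kept; reported values are clamped to [0, 1].
- Duplicate merging is single-linkage over pairs with IBS ≥ 0.99
  (replicate samples differing only by residual heterozygosity and error
  stay above it; unrelated inbreds stay well below). The consensus call is
  the unanimous non-missing member call, missing on conflict, so
  consensus coverage is at least any member's.
- Ordination defaults to classical metric PCoA (Gower double-centering +
  eigendecomposition) on 1 − IBS. A non-metric mode (SMACOF initialized
  from the metric solution) approximates stress-minimizing MDS;
  equivalence between the two is not claimed.

## Diversity conventions

- Allele presence uses a two-carrier rule: an allele counts as present in
  a group only when ≥ 2 distinct samples carry it (a het carries both),
  suppressing singleton sequencing errors in sharing percentages.
- Weir–Cockerham θ uses the haploid ANOVA components given in the README;
  window values are unweighted means of per-site θ ("average per window"),
  with the multi-locus ratio of sums also provided because the two differ:
  per-site ratios are noisy and their mean is biased low relative to the
  ratio of sums, which is the genome-wide estimate of record here. Sites
  with < 2 called haploid samples in either group are skipped.
- Windowed divergence is 1 − mean cross-group pair IBS per 1 Mb window,
  excluding pair-windows with < 10 joint sites (too few calls to estimate
  a proportion). Same-group input uses within-group pairs.
- Haplotype-length sampling: a draw picks a random focal site and random
  line pair; extension skips sites missing in either line (treating them
  as mismatches would confound missingness with diversity); one mismatch
  per side is forgiven (absorbing isolated base-call errors), the second
  ends the side; a mismatch at the focal site itself consumes the
  allowance of both sides, and with forgiveness disabled such a draw has
  length 1. Length is reported both as sites (focal + matching compared
  sites; forgiven mismatches do not count) and as bp (inclusive span of
  the terminal matching sites). Draws are assigned to genome intervals by
  the position of the middle site of the shared interval. No
  allele-frequency filtering is applied beforehand. The exact accounting
  of the focal site and the forgiven mismatch is pinned by an enumeration
  oracle in the tests: with forgiveness off, the sampler equals maximal
  shared-interval enumeration.
- LD decay filters sites with > 25% missing data or MAF < 0.05 within the
  group, subsamples 180 lines (all lines when the group is smaller),
  computes pairwise-complete r² for within-chromosome pairs up to the
  distance cap, and summarizes per distance bin (mean, median, 50% and
  90% bands). Bins are log-spaced by default (LD decays roughly
  geometrically) with a linear option. Note the null floor: independent
  sites give E[r²] ≈ 1/n at sample size n.
- Window rank correlations are Spearman with mid-ranked ties, reported
  with ρ² alongside ρ; fewer than 3 complete pairs is undefined.

## Validation problem sizes

The test suite and acceptance script run at desk scale, chosen so each
statistic has enough data to separate signal from its own sampling noise:
three-group panels of 60 lines/group × 5,000 sites for Fst recovery
(bootstrap over sites), 1,000 pedigree replicates for the backcross
expectation, a 42-line panel duplicated and masked to 35% coverage for
imputation (≈ 39,000 scored cells), 10,000-site block pairs × 500 draws
for haplotype length, and 100,000 calls for error-rate recovery. The full
suite runs in well under a minute; the acceptance script in seconds.

## Known limitations

- The generator's drift model is exchangeable across sites; real panels
  couple allele frequency, recombination and missingness along the genome.
- The imputation donor search is within the supplied panel, not an
  external database; reported unimputed fractions are therefore not
  comparable to pipelines searching tens of thousands of candidate donors.
- The outbred IBD mode is retained for heterozygous material but is the
  wrong choice for inbred panels (see above).
- Non-metric ordination minimizes SMACOF stress on ranks; it is an
  approximation to, not a re-implementation of, any particular isoMDS
  routine.
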