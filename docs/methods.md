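# Methods

## Fragment model

A displayable fragment is the genomic insert between a primary-enzyme cut
and the nearest CCGG cut, with no other CCGG in between.  All coordinates
are 0-based half-open internally; only user-facing locus labels and the
monitored CpG position are 1-based.  For a primary site starting at `p`
(recognition length `Lp`, top-strand cut offset `cp`) and a secondary
site at `s` (length `Ls`, offset `cs`):

* `+` fragment: insert `[p + cp, s + cs)` — both ends at top-strand cuts;
* `-` fragment: insert `[s + (Ls − cs), p + (Lp − cp))` — both ends at
  bottom-strand cuts.

This pairing was chosen because it is exactly mirror-symmetric: reverse-
complementing the genome maps every `+` fragment onto a `-` fragment with
identical insert length, selective bases and monitored CpG, so neither
strand is privileged.  (Mixing a top-strand cut at one end with a
bottom-strand cut at the other would break this symmetry; with sticky-end
enzymes any single-strand convention is partly arbitrary, and the constant
few-base difference is absorbed by `display_offset` below.)  The property
is asserted in the test suite, and the whole digest is cross-checked
fragment-for-fragment against a brute-force string-scanning oracle on
hundreds of random genomes.

A fragment is emitted only when (a) a secondary cut exists between the
primary cut and the neighbouring primary cut (or chromosome end), (b) its
display length lies within `size_range`, and (c) its selective bases are
defined and N-free.  When two primary sites share one CCGG from opposite
sides, both fragments are kept — they are distinct molecules.

**Display length** = insert length + `display_offset`.  The offset (one
configurable integer, default 0) absorbs the constant adaptor/primer bases
present in the electrophoresed product; with the default, sizes read as
genomic lengths.  Default `size_range` is [50, 500] nt, the sizing range
of the 500-nt size standard used on capillary sequencers; both bounds are
configurable.  Because it is ambiguous whether published fragment counts
refer to pre- or post-size-filter sets, the database records both counts.

**Selective bases.**  On the fragment strand the insert begins with the
primary remnant (GG for SbfI) and ends with the secondary remnant (C for
CCGG).  `sel_primary` is the two bases 3′ of the primary remnant read on
the fragment strand; `sel_secondary` is the two bases 5′ of the secondary
remnant read on the opposite strand (the strand the MspI-side primer
extends), i.e. their reverse complement.  The convention used by the
original online locus-prediction service is unpublished; ours is fixed,
documented, and applied identically in the oracle.

**Monitored CpG** = internal C of the nearest CCGG, reported 1-based as
`s + 2` for both orientations; methylation profiles are keyed on the
forward-strand C, treating the CpG dyad as one unit.

**Uniqueness.**  Within one selective subset (= one electropherogram) a
fragment is "single peak" iff no other subset member shares its integer
display length (1-nt binning; the instrument's binning is unpublished, so
this is the declared convention).  Co-migration across subsets is
irrelevant as those fragments never share a run.

## Library chemistry simulator

Expected fragment abundance:

```
A = eff_primary · eff_mspi · (m + (1 − m)(1 − eff_hpaii))
```

where `m` is the monitored CpG's methylation level.  All efficiencies
default to 1 (vendor-guaranteed complete digestion; methylation blocks
HpaII completely), reducing to `A = m`.  Hemi-methylated sites are treated
as fully protected.  Abundances are continuous expectations; a binomial
sampling mode exists for finite-copy qPCR simulations.

Peak model, per selective subset: abundances of fragments sharing an
integer display length are summed (co-migration), then

* intensity = `gain · A · exp(N(0, noise_sigma²))`, default gain 1000 RFU
  per unit abundance;
* reported size = display length + `N(0, size_jitter_sd²)`, default
  0.15 nt;
* peaks below `detection_threshold` (default 20 RFU, 2% of full scale)
  are not called.

`noise_sigma` defaults to 0.05: multiplicative log-normal noise at ~5% CV
keeps duplicate-library scatter mostly within a 1.1-fold band and yields a
between-replicate intensity R² of ≈ 0.98 (measured by the validation
suite), the reproducibility regime the wet assay operates in.  Not modeled: PCR saturation
across the pre-/selective-PCR cycles, length-dependent amplification bias,
dye spectra, stutter.  The SssI reference chart is the same simulation
with every level forced to 1.

The paired-digest qPCR simulation returns
`(copies·[m + (1−m)(1−eff_hpaii)], copies)` for the HpaII and control
(StuI) aliquots, each with log-normal qPCR noise; percent methylation is
100 × their ratio, clamped to [0, 100].

## Quantification

Peaks from replicate charts of one subset are matched by single-linkage
clustering on size, splitting wherever consecutive sorted sizes are more
than 0.5 nt apart (capillary sizing precision; the published workflow does
not state its matching rule).  A sample absent from a bin scores 0
intensity and is flagged; a sample contributing two peaks keeps the taller
with a warning.  SR = sample intensity / SssI-reference intensity per bin;
bins with zero reference are dropped and reported.  SR > 1 is preserved in
the SR table (diagnostics) and only clamped at the percent stage.

The calibration `M(SR) = 100·SRʰ/(Kʰ + SRʰ)` fixes the maximal response at
100% and baseline at 0 — the curve's job is to normalize SR onto [0, 100],
and two free parameters is as much as ~11 calibration points support.  The
fit is least squares on the percent scale over `(log h, log K)` (enforcing
positivity), multi-started at h ∈ {0.5, 1, 2, 4} with K at the median SR,
keeping the best optimum.  `M` is strictly increasing, `M(K) = 50`
exactly.  Calibration points pair each locus's SR with the paired-digest
qPCR percent of the same sample; per-sample points are the default (an
averaged-replicate mode is a caller-side choice, since whether replicates
were pooled before fitting is unpublished).

## Differential statistics

Per CpG: classical one-way fixed-effects ANOVA, vectorized across rows; BH
step-up across all CpGs of the batch jointly (all selective subsets
pooled, mirroring a single pooled analysis); significant iff q ≤ 0.05.
Rows with no variance at all are reported with p = 1 and flagged; a 1e-12
variance floor keeps F finite when groups are internally constant but
differ.  Tukey HSD (studentized range; Tukey–Kramer for unequal n) runs by
default on the ANOVA-significant rows, following the published two-stage
description; per pair it reports Δ = |difference of group mean percents|
and ρ = max/min of group mean percents (denominator floored at 0.1
points), so ρ ≥ 1 and "1.1-fold" is orientation-free.  The subtle filter
keeps Tukey-significant pairs with Δ < 5 and ρ < 1.1.  z-scores use row
mean/SD across all samples with the n−1 denominator; zero-variance rows
are dropped and listed.  PCA operates on samples in z-score space
(scikit-learn); UPGMA is average-linkage hierarchical clustering on
Euclidean sample distances (scipy), exported as newick.

## Synthetic data

Genomes: i.i.d. background at a set GC fraction (default 0.42,
mouse-like) with SbfI and CCGG motifs planted at non-overlapping random
positions.  Truth is defined by re-scanning the generated sequence, so
accidental motifs count as real sites and the truth tables agree exactly
with any scanner.  Defaults: 2 chromosomes × 500 kb, 150 planted SbfI
sites per chromosome, 3.3 CCGG/kb — a few hundred displayable fragments,
comparable per-megabase site density to a mammalian genome, sized to run
in seconds.

Studies: baseline level per CpG ~ Beta(2, 10), i.e. mostly low
methylation with a tail toward 50%+.  This low-skewed choice reflects the
CpG-island-proximal CpGs that a CpG-containing rare cutter (CCTGCAGG)
combined with CCGG enriches; it also keeps the assay's informative
dynamic range (SR well below saturation) populated.  Default effects: 50
planted CpGs, +5 percentage points in one tissue (cycled across tissues).
Replicate noise is additive Gaussian on the level scale, default SD 0.01
(≈ 1 point): a ~5% intensity CV between duplicate libraries corresponds to
about 1 point at typical levels, and biological replicates of inbred
animals add little more.  The operating-characteristics simulations
instead apply the chart-level multiplicative noise (σ = 0.05) directly on
the percent scale, which is the noise actually propagated through the
chemistry.

What passing tests on these fixtures do *not* show: robustness to repeat
sequences and mapping ambiguity, CpG-island methylation autocorrelation,
bimodal methylomes, batch effects, or instrument artifacts (pull-up,
stutter, baseline drift) — none of which the generator emulates.

## Numerical and scale choices

* Validation sizes: digest oracle on 200 × 50 kb genomes; end-to-end
  recovery on the default 1 Mb fixture (~3,700 quantified cells);
  replicate R² on a 3 Mb genome (~2,300 peaks, tightening the sampling
  error of the estimate); FDR/power on 200 simulated studies of 2,000
  CpGs each.  Everything runs in seconds on one core.
* The null-FDR estimate over 200 studies has a sampling SD of ≈ 0.015
  around its expectation of 0.05 (under a complete null the realized FDP
  is 0 or 1 per study), so individual 200-run estimates near 0.06 are
  expected behaviour, not drift.
* Hill fitting tolerances are set to machine precision (`xtol = ftol =
  gtol = 1e-15`) so noiseless calibration points are recovered exactly.
* Degenerate inputs: empty genomes/databases, single groups, all-constant
  matrices, zero-reference bins, sub-4-nt inserts and N-containing
  selective bases all raise explicit errors or are excluded with logged
  warnings, as documented per function.

## Known limitations

* Only palindromic recognition sequences are supported (all shipped
  enzymes are palindromic); non-palindromic enzymes error out rather than
  silently half-scanning.
* Genome-wide motif counts are assembly-dependent; no assembly is bundled
  or assumed.
* The Hill curve cannot represent a strictly linear SR→percent
  relationship; with fully linear synthetic data the fit is an
  approximation whose error is small in the low-methylation regime the
  default study populates (end-to-end MAE ≈ 1.5–2 points) and grows
  toward high SR.
* Fragments co-migrating within a subset are quantified as one summed
  peak; their individual levels are not recoverable by design.
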