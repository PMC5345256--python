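# msdaflp

In-silico **methylated site display AFLP**: a toolchain for
methylation-sensitive restriction profiling of CpG methylation by selective
fragment amplification.

## The problem and who this is for

Methylated site display (MSD) library preparation keeps only those genomic
restriction fragments whose terminal CCGG-CpG was methylated in the source
DNA: the genome is cut with a rare-cutting primary enzyme (SbfI), the other
end is trimmed to the nearest CCGG with MspI, and a final digestion with the
methylation-sensitive isoschizomer HpaII removes the second adaptor from
every fragment whose CpG was unmethylated.  Selective PCR with 16 × 16
two-base primer extensions then splits the surviving fragments into 256
subsets small enough to read as individual peaks on a capillary
electropherogram (AFLP).  Peak intensity is proportional to the methylation
level of one identifiable CpG, so the method measures percent methylation at
tens of thousands of CpGs per genome at qPCR-like precision and modest cost.

This package is for epigenetics researchers who want to **design, simulate,
and analyze** such experiments without wet-lab or reference-data
dependencies.  It provides:

* **`genome_io`** — FASTA/BED/GFF3 I/O, IUPAC restriction-site scanning, a
  user-extensible plain-text enzyme table (SbfI, HpaII/MspI, StuI, NcoI,
  AseI, BspHI, PacI, SwaI shipped).
* **`fragment_db`** — the virtual fragment database: every
  SbfI-to-nearest-CCGG fragment with its display size, selective
  dinucleotides and monitored CpG; size-uniqueness statistics; candidate
  locus prediction from an observed peak (subset + size → loci); intragenic
  fractions.
* **`simulate`** — a forward simulator of the library chemistry producing
  noisy peak charts, including the SssI fully methylated reference and the
  paired-digest (HpaII vs StuI) qPCR measurement.
* **`quantify`** — peak matching across samples, signal ratios (SR) against
  the SssI reference, and the Hill calibration
  `M(SR) = 100·SRʰ/(Kʰ + SRʰ)` mapping SR onto percent methylation.
* **`diff_meth`** — one-way ANOVA with Benjamini–Hochberg FDR, Tukey HSD
  with Δ (percentage-point) and ρ (fold) effect sizes, the "subtle
  difference" filter (Δ < 5, ρ < 1.1), and z-score/PCA/UPGMA summaries.
* **`synthetic`** — generators for genomes with planted restriction sites,
  multi-tissue methylome studies with known truth, and self-contained
  fixture bundles.

A `msdaflp` command-line interface wraps the common workflows
(`build-db`, `query`, `stats`, `simulate`, `quantify`, `diff`, `fixture`).

## Worked example

Generate a complete synthetic study (2 × 500 kb genome, 3 tissues × 3
replicates, 50 planted 5-point effects), quantify it, and test for
differential methylation:

```python
import pandas as pd
from msdaflp import *

bundle = make_fixture(
    "demo",
    genome_spec=SynthGenomeSpec(seed=11),
    study_spec=SynthStudySpec(seed=12),
    sim_params=SimParams(seed=13),
)
print("fragments:", len(bundle.db))
rep = uniqueness_report(bundle.db)
print(f"single-peak: {rep.n_single_peak}/{rep.total_fragments} = {100*rep.fraction:.1f}%")

cal = fit_hill(bundle.calibration[["sr", "msre_percent"]])
print(f"Hill fit: h={cal.h:.3f} K={cal.K:.3f} rmse={cal.rmse:.2f}")

by_subset = {}
for c in bundle.charts:
    by_subset.setdefault((c.sel_primary, c.sel_secondary), []).append(c)
frames = []
for _, charts in sorted(by_subset.items()):
    t = match_peaks(charts, 0.5)
    if "SssI" in t.table.columns:
        frames.append(charts_to_percent(t, "SssI", cal, db=bundle.db))
matrix = pd.concat(frames)

samples = bundle.study.samples
res = anova_bh(matrix[samples], bundle.study.groups)
print("significant CpGs:", int(res.significant.sum()), "of", len(res))
```

prints

```
fragments: 399
single-peak: 395/399 = 99.0%
Hill fit: h=1.591 K=0.493 rmse=2.20
significant CpGs: 32 of 397
```

399 displayable fragments were predicted from the synthetic genome, and 99%
of them occupy a unique size within their selective subset, i.e. they
resolve as single peaks.  The Hill calibration (fitted on 11 loci pairing
chart SR with simulated paired-digest qPCR percents) converts every peak to
percent methylation; the ANOVA/BH stage then recovers 32 differential CpGs
at q ≤ 0.05 — about the expected 60–65% power for 5-percentage-point
effects with three replicates.  One recovered row reads

```
candidate_loci    chr2:298714
liver_1             40.06
liver_2             38.56
liver_3             42.54
```

against true simulated liver levels of 40.8 / 39.6 / 40.3% — the
quantification chain recovers levels to within ~2 percentage points on
average.  `tukey_hsd` + `subtle_filter` attribute significant differences
to tissue pairs and isolate those below 5 points and 1.1-fold, and
`zscore_pca_cluster` returns PCA scores and a UPGMA newick tree in which
replicates of the same tissue cluster together.

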