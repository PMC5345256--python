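"""Synthetic genomes, methylomes and complete studies with known truth.

The generator emulates the structure the assay sees — primary restriction
sites scattered over chromosomes, CCGG sites at a chosen density, per-CpG
methylation levels shared across tissues with planted tissue effects — so
every downstream module can be exercised end to end without any external
genome.  Two deliberate simplifications: background sequence is i.i.d.
(no repeats, no CpG-island clustering), and methylation levels carry no
spatial autocorrelation.

Truth is defined by re-scanning the generated sequence, not by the
planting plan: motifs that arise by chance in the random background are
real sites and are honored as such, which keeps the emitted truth tables
in exact agreement with what any scanner finds in the FASTA.

Study defaults mirror a three-tissue design with three biological
replicates per tissue, baseline per-CpG levels drawn from Beta(2, 10) — a
low-skewed distribution typical of the CpG-island-proximal CpGs this
enzyme pair enriches — 50 planted 5-percentage-point tissue effects, and
1-point replicate noise on the level scale (consistent with the ~5%
intensity CV of duplicate library preparations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .genome_io import Genome, find_sites, get_enzyme
from .fragment_db import FragmentDB, build_db
from .simulate import (
    MethylationProfile,
    PeakChart,
    SimParams,
    simulate_library,
    simulate_msre,
    simulate_peak_chart,
    write_charts,
)

__all__ = [
    "SynthGenomeSpec",
    "SynthStudySpec",
    "StudyTruth",
    "FixtureBundle",
    "generate_genome",
    "generate_study",
    "make_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Parameters of a planted-motif random genome."""

    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    sbfi_per_chromosome: int = 150
    ccgg_per_kb: float = 3.3
    gc_fraction: float = 0.42
    seed: int = 0
    primary_motif: str = "CCTGCAGG"

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need >= 1 chromosome")
        if self.chromosome_length < 1000:
            raise ValueError("chromosome length must be >= 1 kb")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("GC fraction must be in [0, 1]")
        planted = self.sbfi_per_chromosome * len(self.primary_motif) + int(
            self.ccgg_per_kb * self.chromosome_length / 1000
        ) * 4
        if planted > 0.3 * self.chromosome_length:
            raise ValueError(
                f"unsatisfiable spec: {planted} planted bases on a "
                f"{self.chromosome_length} nt chromosome"
            )


def generate_genome(spec: SynthGenomeSpec) -> tuple[Genome, dict]:
    """Random genome with planted SbfI and CCGG motifs, plus realized truth.

    Returns ``(genome, truth)`` where ``truth`` lists the *realized*
    (re-scanned) site starts per chromosome for the primary motif and
    CCGG — planted and accidental sites alike.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    p_bases = np.array(
        [
            (1 - spec.gc_fraction) / 2,
            spec.gc_fraction / 2,
            spec.gc_fraction / 2,
            (1 - spec.gc_fraction) / 2,
        ]
    )
    chroms: dict[str, str] = {}
    for ci in range(spec.n_chromosomes):
        length = spec.chromosome_length
        seq = rng.choice(_BASES, size=length, p=p_bases)
        occupied = np.zeros(length, dtype=bool)

        def plant(motif: str, count: int) -> None:
            arr = np.array(list(motif))
            width = len(motif)
            planted = 0
            attempts = 0
            while planted < count and attempts < count * 200:
                attempts += 1
                pos = int(rng.integers(0, length - width))
                if occupied[pos : pos + width].any():
                    continue
                seq[pos : pos + width] = arr
                occupied[pos : pos + width] = True
                planted += 1
            if planted < count:
                raise ValueError(
                    f"could not place {count} copies of {motif} "
                    f"(placed {planted}); spec too dense"
                )

        plant(spec.primary_motif, spec.sbfi_per_chromosome)
        plant("CCGG", int(round(spec.ccgg_per_kb * length / 1000)))
        chroms[f"chr{ci + 1}"] = "".join(seq)

    genome = Genome(chroms)
    # realized truth by re-scan: accidental motifs are real sites
    primary = get_enzyme("SbfI")
    if primary.recognition != spec.primary_motif:
        from .genome_io import EnzymeSpec

        primary = EnzymeSpec("custom", spec.primary_motif, len(spec.primary_motif) // 2)
    truth = {
        "primary_sites": {
            chrom: [
                h.site_start
                for h in find_sites(genome, primary)
                if h.chromosome_name == chrom
            ]
            for chrom in genome
        },
        "ccgg_sites": {
            chrom: [
                h.site_start
                for h in find_sites(genome, get_enzyme("HpaII"))
                if h.chromosome_name == chrom
            ]
            for chrom in genome
        },
    }
    return genome, truth


@dataclass(frozen=True)
class SynthStudySpec:
    """A multi-tissue replicated methylation study design."""

    tissues: tuple[str, ...] = ("liver", "kidney", "hippocampus")
    replicates: int = 3
    beta_a: float = 2.0
    beta_b: float = 10.0
    n_planted: int = 50
    effect_size: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0
    planted_cpgs: tuple | None = None  # explicit (chrom, pos) selectors

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("need >= 2 tissues")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate per tissue")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta parameters must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class StudyTruth:
    """Ground truth of a generated study."""

    profiles: dict[str, MethylationProfile]
    groups: dict[str, str]  # sample -> tissue
    tissue_means: pd.DataFrame  # rows = CpGs, columns = tissues
    planted: pd.DataFrame  # chrom, pos, tissue, delta
    levels: pd.DataFrame  # rows = CpGs, columns = samples (realized levels)

    @property
    def samples(self) -> list[str]:
        return list(self.profiles)


def generate_study(db: FragmentDB, spec: SynthStudySpec) -> StudyTruth:
    """Per-sample methylation profiles with planted tissue effects.

    Baseline per CpG ~ Beta(a, b) shared across tissues; planted CpGs get
    a per-tissue delta added to the mean; each replicate adds Gaussian
    level-scale noise.  All levels are clamped to [0, 1] after effects.
    """
    if not len(db):
        raise ValueError("empty fragment database")
    cpgs = sorted({f.cpg_key for f in db})
    rng = np.random.default_rng(spec.seed)
    baseline = rng.beta(spec.beta_a, spec.beta_b, size=len(cpgs))

    if spec.planted_cpgs is not None:
        cpg_index = {c: i for i, c in enumerate(cpgs)}
        missing = [c for c in spec.planted_cpgs if tuple(c) not in cpg_index]
        if missing:
            raise ValueError(f"planted selectors match no CpG: {missing}")
        planted_idx = np.array([cpg_index[tuple(c)] for c in spec.planted_cpgs])
    elif spec.n_planted > 0:
        if spec.n_planted > len(cpgs):
            raise ValueError(
                f"cannot plant {spec.n_planted} effects in {len(cpgs)} CpGs"
            )
        planted_idx = rng.choice(len(cpgs), size=spec.n_planted, replace=False)
    else:
        planted_idx = np.array([], dtype=int)

    tissues = list(spec.tissues)
    means = np.tile(baseline[:, None], (1, len(tissues)))
    planted_rows = []
    for j, idx in enumerate(np.sort(planted_idx)):
        tissue_j = j % len(tissues)  # cycle the affected tissue
        means[idx, tissue_j] += spec.effect_size
        planted_rows.append(
            (cpgs[idx][0], cpgs[idx][1], tissues[tissue_j], spec.effect_size)
        )
    means = np.clip(means, 0.0, 1.0)

    profiles: dict[str, MethylationProfile] = {}
    groups: dict[str, str] = {}
    level_cols: dict[str, np.ndarray] = {}
    for t, tissue in enumerate(tissues):
        for r in range(spec.replicates):
            sample = f"{tissue}_{r + 1}"
            levels = means[:, t]
            if spec.noise_sd > 0:
                levels = levels + rng.normal(0.0, spec.noise_sd, size=len(cpgs))
            levels = np.clip(levels, 0.0, 1.0)
            profiles[sample] = MethylationProfile(
                dict(zip(cpgs, levels.astype(float)))
            )
            groups[sample] = tissue
            level_cols[sample] = levels

    index = pd.MultiIndex.from_tuples(cpgs, names=["chromosome", "position"])
    return StudyTruth(
        profiles=profiles,
        groups=groups,
        tissue_means=pd.DataFrame(means, index=index, columns=tissues),
        planted=pd.DataFrame(
            planted_rows, columns=["chromosome", "position", "tissue", "delta"]
        ),
        levels=pd.DataFrame(level_cols, index=index),
    )


@dataclass
class FixtureBundle:
    """A self-contained on-disk study plus the in-memory objects."""

    outdir: Path
    genome: Genome
    db: FragmentDB
    study: StudyTruth
    charts: list[PeakChart]
    reference_sample: str
    calibration: pd.DataFrame
    manifest: dict


def _chart_seed(state: np.ndarray, i: int) -> int:
    return int(state[i % len(state)] % (2**31))


def make_fixture(
    outdir: str | Path,
    genome_spec: SynthGenomeSpec = SynthGenomeSpec(),
    study_spec: SynthStudySpec = SynthStudySpec(),
    sim_params: SimParams = SimParams(),
    n_calibration: int = 11,
    size_range: tuple[int, int] = (50, 500),
) -> FixtureBundle:
    """Generate and write a complete reproducible study bundle.

    Writes FASTA, fragment DB TSV, per-sample methylation profiles,
    simulated peak charts for every selective subset of every sample plus
    the SssI reference, a calibration table of ``n_calibration`` loci
    spanning the SR range, truth tables, and a manifest with every seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, site_truth = generate_genome(genome_spec)
    fasta = outdir / "genome.fasta"
    genome.to_fasta(fasta)

    db = build_db(genome, size_range=size_range, genome_label="synthetic")
    if not len(db):
        raise ValueError("generated genome yields no fragments; adjust the spec")
    db.save(outdir / "fragments.tsv")

    study = generate_study(db, study_spec)
    profile_dir = outdir / "profiles"
    profile_dir.mkdir(exist_ok=True)
    for sample, profile in study.profiles.items():
        profile.to_tsv(profile_dir / f"{sample}.tsv")

    # one chart per (sample, selective subset); independent seeds throughout
    seed_state = np.random.SeedSequence(sim_params.seed).generate_state(
        (len(study.profiles) + 1) * len(db.subsets) + 2 * n_calibration + 16
    )
    charts: list[PeakChart] = []
    counter = 0
    reference_sample = "SssI"
    full = MethylationProfile.fully_methylated(db)
    for sample, profile in list(study.profiles.items()) + [(reference_sample, full)]:
        library = simulate_library(db, profile, sim_params)
        for sp, ss in sorted(db.subsets):
            charts.append(
                simulate_peak_chart(
                    library, sp, ss,
                    sim_params.with_seed(_chart_seed(seed_state, counter)),
                    sample=sample,
                )
            )
            counter += 1
    write_charts(charts, outdir / "charts.csv")

    calibration = _calibration_table(
        db, study, charts, reference_sample, sim_params, seed_state, counter,
        n_calibration,
    )
    calibration.to_csv(outdir / "calibration.tsv", sep="\t", index=False)

    study.levels.to_csv(outdir / "true_levels.tsv", sep="\t")
    study.planted.to_csv(outdir / "planted_effects.tsv", sep="\t", index=False)

    manifest = {
        "genome_spec": asdict(genome_spec),
        "study_spec": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(study_spec).items()
        },
        "sim_params": asdict(sim_params),
        "n_calibration": n_calibration,
        "size_range": list(size_range),
        "reference_sample": reference_sample,
        "n_fragments": len(db),
        "n_primary_sites": {
            c: len(v) for c, v in site_truth["primary_sites"].items()
        },
        "n_ccgg_sites": {c: len(v) for c, v in site_truth["ccgg_sites"].items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return FixtureBundle(
        outdir=outdir,
        genome=genome,
        db=db,
        study=study,
        charts=charts,
        reference_sample=reference_sample,
        calibration=calibration,
        manifest=manifest,
    )


def _calibration_table(
    db: FragmentDB,
    study: StudyTruth,
    charts: list[PeakChart],
    reference_sample: str,
    sim_params: SimParams,
    seed_state: np.ndarray,
    counter: int,
    n_calibration: int,
) -> pd.DataFrame:
    """Calibration loci spanning the SR range, measured like the assay does.

    Picks non-co-migrating fragments whose levels in the calibration sample
    span the observed range, reads their SR off the simulated charts, and
    pairs it with a simulated paired-digest qPCR percent of the same
    sample.
    """
    cal_sample = study.samples[0]
    profile = study.profiles[cal_sample]

    # fragments with a unique display length within their subset
    unique_frags = []
    for (sp, ss), frags in db.subsets.items():
        counts: dict[int, int] = {}
        for f in frags:
            counts[f.display_length] = counts.get(f.display_length, 0) + 1
        unique_frags.extend(f for f in frags if counts[f.display_length] == 1)
    if len(unique_frags) < n_calibration:
        raise ValueError("too few non-co-migrating fragments for calibration")
    unique_frags.sort(key=lambda f: profile.get(f.cpg_key, 0.0))
    pick = np.unique(
        np.linspace(0, len(unique_frags) - 1, n_calibration).round().astype(int)
    )
    chosen = [unique_frags[i] for i in pick]

    by_key = {(c.sample, c.sel_primary, c.sel_secondary): c for c in charts}

    def peak_height(sample: str, frag) -> float:
        chart = by_key[(sample, frag.sel_primary, frag.sel_secondary)]
        for size, height in chart.peaks:
            if abs(size - frag.display_length) <= 0.5:
                return height
        return 0.0

    rows = []
    for i, frag in enumerate(chosen):
        ref = peak_height(reference_sample, frag)
        if ref <= 0:
            continue
        sr = peak_height(cal_sample, frag) / ref
        msre_seed = _chart_seed(seed_state, counter + i)
        ch, cs = simulate_msre(
            profile, frag.cpg_key, 10_000.0, sim_params.with_seed(msre_seed)
        )
        from .quantify import msre_percent

        rows.append((frag.locus_label, sr, msre_percent(ch, cs)))
    return pd.DataFrame(rows, columns=["locus", "sr", "msre_percent"])
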