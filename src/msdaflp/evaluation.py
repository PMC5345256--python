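"""End-to-end validation routines with independent oracles.

Each function here re-derives one headline property of the toolchain from
scratch — digest prediction against a brute-force scan, locus-query round
trips, noise-free quantification identities, Hill-calibration recovery,
whole-study level recovery, replicate reproducibility, and the false
discovery / power operating characteristics of the differential pipeline.
They are used by the test suite and by ``scripts/acceptance.py``.

The digest oracle deliberately avoids the production code paths: it finds
motifs with ``str.find``, locates nearest neighbours by linear scan, and
extracts selective bases by direct string indexing, so agreement with
:func:`msdaflp.fragment_db.build_db` is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_io import Genome, revcomp
from .fragment_db import FragmentDB, build_db, query_loci, uniqueness_report
from .simulate import (
    MethylationProfile,
    SimParams,
    simulate_library,
    simulate_peak_chart,
    simulate_reference_chart,
)
from .quantify import (
    HillCalibration,
    fit_hill,
    hill_percent,
    match_peaks,
    signal_ratio,
)
from .diff_meth import anova_bh
from .synthetic import (
    FixtureBundle,
    SynthGenomeSpec,
    SynthStudySpec,
    generate_genome,
    make_fixture,
)

__all__ = [
    "oracle_digest",
    "digest_oracle_check",
    "locus_roundtrip",
    "noise_free_sr_identity",
    "hill_law_pipeline_error",
    "hill_recovery",
    "make_default_bundle",
    "end_to_end_recovery",
    "replicate_r2",
    "operating_characteristics",
]

NOISELESS = SimParams(noise_sigma=0.0, size_jitter_sd=0.0, detection_threshold=0.0)


# ---------------------------------------------------------------------------
# digest oracle


def _find_all(seq: str, motif: str) -> list[int]:
    out = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)  # overlapping occurrences
    return out


def oracle_digest(
    genome: Genome, size_range: tuple[int, int] = (50, 500)
) -> set[tuple]:
    """Brute-force SbfI/CCGG digest; returns fragment tuples for comparison.

    Tuple layout: (chrom, orientation, insert_start, insert_end,
    display_length, sel_primary, sel_secondary, cpg_pos).
    """
    frags: set[tuple] = set()
    for chrom, seq in genome.items():
        ps = _find_all(seq, "CCTGCAGG")
        ss = _find_all(seq, "CCGG")
        for i, p in enumerate(ps):
            nxt = ps[i + 1] if i + 1 < len(ps) else None
            prv = ps[i - 1] if i > 0 else None

            # "+": nearest CCGG whose top cut (s+1) is right of p+6
            plus = [s for s in ss if s + 1 > p + 6]
            if plus:
                s = min(plus)
                if nxt is None or s + 1 <= nxt + 6:
                    start, end = p + 6, s + 1
                    L = end - start
                    if size_range[0] <= L <= size_range[1] and L >= 4:
                        sp = seq[p + 8 : p + 10]
                        sec = revcomp(seq[s - 2 : s])
                        if len(sp) == 2 and len(sec) == 2 and "N" not in sp + sec:
                            frags.add(
                                (chrom, "+", start, end, L, sp, sec, s + 2)
                            )

            # "-": nearest CCGG whose bottom cut (s+3) is left of p+2
            minus = [s for s in ss if s + 3 < p + 2]
            if minus:
                s = max(minus)
                if prv is None or s + 3 >= prv + 2:
                    start, end = s + 3, p + 2
                    L = end - start
                    if size_range[0] <= L <= size_range[1] and L >= 4:
                        sp = revcomp(seq[p - 2 : p])
                        sec = seq[s + 4 : s + 6]
                        if len(sp) == 2 and len(sec) == 2 and "N" not in sp + sec:
                            frags.add(
                                (chrom, "-", start, end, L, sp, sec, s + 2)
                            )
    return frags


def _db_tuples(db: FragmentDB) -> set[tuple]:
    return {
        (
            f.chromosome_name,
            f.orientation,
            f.insert_start,
            f.insert_end,
            f.display_length,
            f.sel_primary,
            f.sel_secondary,
            f.cpg_pos,
        )
        for f in db
    }


def digest_oracle_check(
    n_genomes: int = 200,
    chromosome_length: int = 50_000,
    seed: int = 0,
) -> dict:
    """Compare build_db to the brute-force oracle on random genomes."""
    seeds = np.random.SeedSequence(seed).generate_state(n_genomes) % (2**31)
    n_agree = 0
    n_fragments = 0
    for s in seeds:
        spec = SynthGenomeSpec(
            n_chromosomes=1,
            chromosome_length=chromosome_length,
            sbfi_per_chromosome=20,
            ccgg_per_kb=4.0,
            gc_fraction=0.42,
            seed=int(s),
        )
        genome, _ = generate_genome(spec)
        db = build_db(genome)
        expected = oracle_digest(genome)
        got = _db_tuples(db)
        n_fragments += len(expected)
        if got == expected:
            n_agree += 1
    return {
        "n_genomes": n_genomes,
        "n_agree": n_agree,
        "agreement_fraction": n_agree / n_genomes,
        "total_oracle_fragments": n_fragments,
    }


# ---------------------------------------------------------------------------
# locus prediction round trip


def locus_roundtrip(db: FragmentDB) -> dict:
    """Query every fragment's own (subset, size); measure recovery and ambiguity."""
    n_hit = 0
    n_candidates_tol1 = 0
    for f in db:
        exact = query_loci(db, f.sel_primary, f.sel_secondary, f.display_length, 0.0)
        if f in exact:
            n_hit += 1
        n_candidates_tol1 += len(
            query_loci(db, f.sel_primary, f.sel_secondary, f.display_length, 1.0)
        )
    n = len(db)
    return {
        "n_fragments": n,
        "recovery_fraction": n_hit / n,
        "mean_candidates_tol1": n_candidates_tol1 / n,
    }


# ---------------------------------------------------------------------------
# quantification identities


def _noise_free_tables(db: FragmentDB, profile: MethylationProfile):
    """Per-subset (SR series, true level map) from noise-free charts."""
    library = simulate_library(db, profile, NOISELESS)
    for (sp, ss), frags in sorted(db.subsets.items()):
        counts: dict[int, int] = {}
        for f in frags:
            counts[f.display_length] = counts.get(f.display_length, 0) + 1
        solo = {f.display_length: f for f in frags if counts[f.display_length] == 1}
        if not solo:
            continue
        sample_chart = simulate_peak_chart(library, sp, ss, NOISELESS, sample="s")
        ref_chart = simulate_reference_chart(db, sp, ss, NOISELESS)
        table = match_peaks([sample_chart, ref_chart], tolerance_nt=0.5)
        sr = signal_ratio(table, "SssI")["s"]
        yield sr, solo


def noise_free_sr_identity(db: FragmentDB, profile: MethylationProfile) -> dict:
    """Max |SR - m| over all non-co-migrating fragments, noise off."""
    max_err = 0.0
    n = 0
    for sr, solo in _noise_free_tables(db, profile):
        for size, value in sr.items():
            frag = solo.get(int(round(size)))
            if frag is None:
                continue
            m = profile[frag.cpg_key]
            max_err = max(max_err, abs(value - m))
            n += 1
    return {"n_fragments": n, "max_abs_error": max_err}


def hill_law_pipeline_error(
    db: FragmentDB,
    profile: MethylationProfile,
    h: float = 2.0,
    K: float = 0.5,
) -> dict:
    """Full noise-free chain against a known calibration law.

    Calibration points lie exactly on a Hill law; the chain
    simulate -> match -> SR -> fit -> percent must then reproduce the
    law's percent for every non-co-migrating fragment.
    """
    law = HillCalibration(h=h, K=K)
    grid = np.linspace(0.05, 1.2, 11)
    cal = fit_hill(list(zip(grid, hill_percent(law, grid))))
    max_err = 0.0
    n = 0
    for sr, solo in _noise_free_tables(db, profile):
        for size, value in sr.items():
            frag = solo.get(int(round(size)))
            if frag is None:
                continue
            true_pct = hill_percent(law, profile[frag.cpg_key])
            got = hill_percent(cal, float(value))
            max_err = max(max_err, abs(got - true_pct))
            n += 1
    return {"n_fragments": n, "max_abs_error_percent": max_err,
            "fitted_h": cal.h, "fitted_K": cal.K}


def hill_recovery(
    seed: int = 0,
    h: float = 2.0,
    K: float = 0.5,
    n_points: int = 11,
    sr_noise_sigma: float = 0.05,
) -> dict:
    """Calibration recovery from noiseless and SR-noisy points.

    Noiseless points on the law must be recovered essentially exactly;
    with multiplicative SR noise the refit curve is evaluated on a clean
    SR grid against the law and summarized as percent RMSE.
    """
    law = HillCalibration(h=h, K=K)
    sr = np.linspace(0.05, 1.2, n_points)
    pct = hill_percent(law, sr)

    clean_fit = fit_hill(list(zip(sr, pct)))
    grid = np.linspace(0.05, 1.2, 200)
    clean_err = float(
        np.max(np.abs(hill_percent(clean_fit, grid) - hill_percent(law, grid)))
    )

    rng = np.random.default_rng(seed)
    sr_noisy = sr * np.exp(rng.normal(0.0, sr_noise_sigma, size=n_points))
    noisy_fit = fit_hill(list(zip(sr_noisy, pct)))
    rmse = float(
        np.sqrt(np.mean((hill_percent(noisy_fit, grid) - hill_percent(law, grid)) ** 2))
    )
    return {
        "n_points": n_points,
        "noiseless_max_abs_error_percent": clean_err,
        "noisy_rmse_percent": rmse,
    }


# ---------------------------------------------------------------------------
# end-to-end study recovery


def make_default_bundle(outdir, seed: int = 0) -> FixtureBundle:
    """The default synthetic study: 2 x 500 kb genome, 3 tissues x 3 reps."""
    return make_fixture(
        outdir,
        genome_spec=SynthGenomeSpec(seed=seed),
        study_spec=SynthStudySpec(seed=seed + 1),
        sim_params=SimParams(seed=seed + 2),
    )


def end_to_end_recovery(bundle: FixtureBundle) -> dict:
    """Recover per-CpG percent levels of a generated study from its charts.

    Fits the Hill calibration on the fixture's calibration table, converts
    every chart bin to percent, maps unambiguous bins (exactly one
    candidate locus) back to their true simulated levels, and reports the
    mean absolute error in percentage points, plus the single-peak
    fraction of the underlying fragment database.
    """
    cal = fit_hill(bundle.calibration[["sr", "msre_percent"]])

    by_subset: dict[tuple[str, str], list] = {}
    for chart in bundle.charts:
        by_subset.setdefault((chart.sel_primary, chart.sel_secondary), []).append(chart)

    errors: list[float] = []
    samples = bundle.study.samples
    levels = bundle.study.levels
    for (sp, ss), charts in sorted(by_subset.items()):
        table = match_peaks(charts, tolerance_nt=0.5)
        if bundle.reference_sample not in table.table.columns:
            continue
        sr = signal_ratio(table, bundle.reference_sample)
        for size, row in sr.iterrows():
            candidates = query_loci(bundle.db, sp, ss, float(size), 0.5)
            if len(candidates) != 1:
                continue
            key = candidates[0].cpg_key
            true_pct = levels.loc[key, samples] * 100.0
            est = hill_percent(cal, row[samples].to_numpy(dtype=float))
            errors.extend(np.abs(est - true_pct.to_numpy(dtype=float)))

    uniq = uniqueness_report(bundle.db)
    return {
        "n_cells": len(errors),
        "mean_abs_error_percent": float(np.mean(errors)),
        "n_fragments": len(bundle.db),
        "single_peak_fraction": uniq.fraction,
        "fitted_h": cal.h,
        "fitted_K": cal.K,
    }


def replicate_r2(seed: int = 0, sigma: float = 0.05) -> dict:
    """Squared Pearson correlation between duplicate library runs.

    One methylome, two independently noised chart sets over a genome large
    enough to give a few thousand peaks; sizing jitter is off so peaks
    pair exactly by display length and the comparison isolates intensity
    reproducibility.
    """
    spec = SynthGenomeSpec(
        n_chromosomes=2,
        chromosome_length=1_500_000,
        sbfi_per_chromosome=1000,
        ccgg_per_kb=6.0,
        gc_fraction=0.42,
        seed=seed,
    )
    genome, _ = generate_genome(spec)
    db = build_db(genome)
    rng = np.random.default_rng(seed + 1)
    cpgs = sorted({f.cpg_key for f in db})
    profile = MethylationProfile(
        dict(zip(cpgs, rng.beta(2.0, 10.0, size=len(cpgs)).astype(float)))
    )
    base = SimParams(noise_sigma=sigma, size_jitter_sd=0.0, detection_threshold=20.0)
    library = simulate_library(db, profile, base)
    seeds = np.random.SeedSequence(seed + 2).generate_state(2 * len(db.subsets)) % (
        2**31
    )
    rep1: dict[tuple, float] = {}
    rep2: dict[tuple, float] = {}
    for i, (sp, ss) in enumerate(sorted(db.subsets)):
        c1 = simulate_peak_chart(library, sp, ss, base.with_seed(int(seeds[2 * i])))
        c2 = simulate_peak_chart(library, sp, ss, base.with_seed(int(seeds[2 * i + 1])))
        for size, height in c1.peaks:
            rep1[(sp, ss, size)] = height
        for size, height in c2.peaks:
            rep2[(sp, ss, size)] = height
    common = sorted(set(rep1) & set(rep2))
    x = np.array([rep1[k] for k in common])
    y = np.array([rep2[k] for k in common])
    r = float(np.corrcoef(x, y)[0, 1])
    return {"n_peaks": len(common), "r2": r * r}


# ---------------------------------------------------------------------------
# statistical operating characteristics


def _simulate_percent_matrix(
    rng: np.random.Generator,
    n_cpgs: int,
    tissues: int,
    reps: int,
    sigma: float,
    beta: tuple[float, float],
    n_planted: int,
    effect: float,
) -> tuple[pd.DataFrame, dict, np.ndarray]:
    """Percent matrix under the assay's multiplicative intensity noise."""
    baseline = rng.beta(beta[0], beta[1], size=n_cpgs)
    means = np.tile(baseline[:, None], (1, tissues))
    planted = np.zeros(n_cpgs, dtype=bool)
    if n_planted:
        idx = rng.choice(n_cpgs, size=n_planted, replace=False)
        planted[idx] = True
        for j, i in enumerate(idx):
            means[i, j % tissues] += effect
    means = np.clip(means, 0.0, 1.0)
    cols = {}
    groups = {}
    for t in range(tissues):
        for r in range(reps):
            sample = f"t{t}_r{r}"
            noise = np.exp(rng.normal(0.0, sigma, size=n_cpgs))
            cols[sample] = 100.0 * np.clip(means[:, t] * noise, 0.0, 1.0)
            groups[sample] = f"t{t}"
    return pd.DataFrame(cols), groups, planted


def operating_characteristics(
    seed: int = 0,
    n_runs: int = 200,
    n_cpgs: int = 2000,
    tissues: int = 3,
    reps: int = 3,
    sigma: float = 0.05,
    beta: tuple[float, float] = (2.0, 10.0),
    n_planted: int = 50,
    effect: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """Realized FDR on complete-null studies and power on planted effects.

    Levels follow the synthetic-study baseline distribution; replicates
    carry the simulator's multiplicative log-normal intensity noise
    propagated to the percent scale.  Each run is an independent study;
    the null runs measure the mean realized false-discovery proportion at
    q <= alpha, the planted runs the mean fraction of planted CpGs
    recovered.
    """
    rng = np.random.default_rng(seed)
    fdp = []
    for _ in range(n_runs):
        matrix, groups, _ = _simulate_percent_matrix(
            rng, n_cpgs, tissues, reps, sigma, beta, 0, 0.0
        )
        res = anova_bh(matrix, groups, alpha=alpha)
        n_rej = int(res["significant"].sum())
        fdp.append(0.0 if n_rej == 0 else 1.0)  # all discoveries are false

    power = []
    for _ in range(n_runs):
        matrix, groups, planted = _simulate_percent_matrix(
            rng, n_cpgs, tissues, reps, sigma, beta, n_planted, effect
        )
        res = anova_bh(matrix, groups, alpha=alpha)
        sig = res["significant"].to_numpy()
        power.append(float(sig[planted].mean()))

    return {
        "n_runs": n_runs,
        "n_cpgs": n_cpgs,
        "realized_fdr": float(np.mean(fdp)),
        "power": float(np.mean(power)),
    }
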