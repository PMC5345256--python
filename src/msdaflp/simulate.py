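"""Forward simulation of the MSD library chemistry and capillary peak charts.

The chemistry in one line: a fragment between a primary cut and the nearest
CCGG survives library preparation (keeps its second adaptor through the
methylation-sensitive HpaII digestion) with probability equal to the
methylation level ``m`` of its monitored CpG, so its expected abundance is

    abundance = eff_primary * eff_mspi * (m + (1 - m) * (1 - eff_hpaii))

which reduces to ``abundance = m`` at complete digestion.  Hemi-methylated
sites are treated as fully protected from HpaII.  Abundances are continuous
expectations, not sampled molecule counts; an optional binomial mode exists
for the qPCR-scale measurements.

Noise model: peak intensities carry multiplicative log-normal noise
(``exp(N(0, noise_sigma^2))``, default sigma 0.05, chosen so duplicate
libraries scatter within roughly a 1.1-fold band like real replicate runs);
peak sizes carry Gaussian sizing jitter (default SD 0.15 nt).  PCR bias is
folded into a single gain; there is no length-dependent efficiency and no
plateau/saturation model.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .fragment_db import FragmentDB, FragmentRecord

__all__ = [
    "MethylationProfile",
    "SimParams",
    "PeakChart",
    "simulate_library",
    "simulate_peak_chart",
    "simulate_reference_chart",
    "simulate_msre",
    "write_charts",
    "read_charts",
]

logger = logging.getLogger(__name__)


@dataclass
class MethylationProfile:
    """Per-CpG methylation fraction in [0, 1], keyed by (chrom, 1-based pos)."""

    levels: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        for key, v in self.levels.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"methylation level {v} at {key} outside [0, 1]")

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.levels[key]

    def __contains__(self, key) -> bool:
        return key in self.levels

    def __len__(self) -> int:
        return len(self.levels)

    def get(self, key, default=None):
        return self.levels.get(key, default)

    @classmethod
    def fully_methylated(cls, db: FragmentDB) -> "MethylationProfile":
        """The SssI-treated reference: every monitored CpG at level 1."""
        return cls({f.cpg_key: 1.0 for f in db})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tposition\tlevel\n")
            for (chrom, pos), v in sorted(self.levels.items()):
                fh.write(f"{chrom}\t{pos}\t{v:.6g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylationProfile":
        levels: dict[tuple[str, int], float] = {}
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                chrom, pos, v = line.rstrip("\n").split("\t")
                levels[(chrom, int(pos))] = float(v)
        return cls(levels)


@dataclass(frozen=True)
class SimParams:
    """Tunable chemistry/instrument parameters.

    eff_* are digestion completenesses in [0, 1]; ``gain`` converts unit
    abundance to RFU; ``noise_sigma`` is the SD of the log-normal intensity
    noise; ``size_jitter_sd`` the SD (nt) of sizing error; peaks below
    ``detection_threshold`` RFU are not called.
    """

    eff_hpaii: float = 1.0
    eff_primary: float = 1.0
    eff_mspi: float = 1.0
    gain: float = 1000.0
    noise_sigma: float = 0.05
    size_jitter_sd: float = 0.15
    detection_threshold: float = 20.0
    seed: int = 0
    missing_level: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eff_hpaii", "eff_primary", "eff_mspi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sigma < 0 or self.size_jitter_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass
class PeakChart:
    """One selective-PCR electropherogram: (size nt, intensity RFU) pairs."""

    sample: str
    sel_primary: str
    sel_secondary: str
    peaks: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None

    @property
    def sizes(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def simulate_library(
    db: FragmentDB,
    profile: MethylationProfile,
    params: SimParams = SimParams(),
) -> dict[FragmentRecord, float]:
    """Expected post-selection abundance of every fragment in ``db``.

    CpGs missing from ``profile`` fall back to ``params.missing_level``
    (default 0) with a warning.
    """
    library: dict[FragmentRecord, float] = {}
    n_missing = 0
    for f in db:
        m = profile.get(f.cpg_key)
        if m is None:
            n_missing += 1
            m = params.missing_level
        library[f] = (
            params.eff_primary
            * params.eff_mspi
            * (m + (1.0 - m) * (1.0 - params.eff_hpaii))
        )
    if n_missing:
        logger.warning(
            "%d of %d monitored CpGs missing from profile; using level %g",
            n_missing, len(db), params.missing_level,
        )
    return library


def simulate_peak_chart(
    library: Mapping[FragmentRecord, float],
    sel_primary: str,
    sel_secondary: str,
    params: SimParams = SimParams(),
    sample: str = "sample",
) -> PeakChart:
    """One noisy electropherogram for one selective primer pair.

    Fragments of the subset that share an integer display length co-migrate
    and their abundances sum into one peak.  Deterministic given
    ``params.seed``.
    """
    by_length: dict[int, float] = {}
    for frag, abundance in library.items():
        if (frag.sel_primary, frag.sel_secondary) != (sel_primary, sel_secondary):
            continue
        by_length[frag.display_length] = by_length.get(frag.display_length, 0.0) + abundance
    rng = np.random.default_rng(params.seed)
    peaks: list[tuple[float, float]] = []
    for length in sorted(by_length):
        abundance = by_length[length]
        intensity = params.gain * abundance
        if params.noise_sigma > 0:
            intensity *= float(np.exp(rng.normal(0.0, params.noise_sigma)))
        size = float(length)
        if params.size_jitter_sd > 0:
            size += float(rng.normal(0.0, params.size_jitter_sd))
        if intensity >= params.detection_threshold:
            peaks.append((size, intensity))
    return PeakChart(sample, sel_primary, sel_secondary, peaks, seed=params.seed)


def simulate_reference_chart(
    db: FragmentDB,
    sel_primary: str,
    sel_secondary: str,
    params: SimParams = SimParams(),
    sample: str = "SssI",
) -> PeakChart:
    """Chart of the artificially fully methylated (SssI) reference DNA."""
    reference = simulate_library(db, MethylationProfile.fully_methylated(db), params)
    return simulate_peak_chart(reference, sel_primary, sel_secondary, params, sample=sample)


def simulate_msre(
    profile: MethylationProfile,
    cpg: tuple[str, int],
    template_copies: float,
    params: SimParams = SimParams(),
    sample_molecules: bool = False,
) -> tuple[float, float]:
    """Simulate the paired-digest qPCR measurement of one CpG.

    One aliquot is digested with methylation-sensitive HpaII, the control
    aliquot with an enzyme cutting none of the targets, and target copies
    surviving each digestion are counted by qPCR.  Returns
    ``(copies_hpaii, copies_control)``; the percent methylation estimate is
    their ratio (see :func:`msdaflp.quantify.msre_percent`).
    """
    if cpg not in profile:
        raise KeyError(f"CpG {cpg} not in profile")
    if template_copies <= 0:
        raise ValueError("template_copies must be > 0")
    m = profile[cpg]
    surviving = m + (1.0 - m) * (1.0 - params.eff_hpaii)
    rng = np.random.default_rng(params.seed)
    if sample_molecules:
        copies_hpaii = float(rng.binomial(int(template_copies), surviving))
    else:
        copies_hpaii = template_copies * surviving
    copies_control = float(template_copies)
    if params.noise_sigma > 0:
        copies_hpaii *= float(np.exp(rng.normal(0.0, params.noise_sigma)))
        copies_control *= float(np.exp(rng.normal(0.0, params.noise_sigma)))
    return copies_hpaii, copies_control


def write_charts(charts: Iterable[PeakChart], path: str | Path) -> None:
    """CSV dialect shared with the peak reader: sample, sel pair, size, height."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample", "sel_primary", "sel_secondary", "size", "height"])
        for chart in charts:
            for size, height in chart.peaks:
                writer.writerow(
                    [chart.sample, chart.sel_primary, chart.sel_secondary,
                     f"{size:.4f}", f"{height:.4f}"]
                )


def read_charts(path: str | Path) -> list[PeakChart]:
    """Read the chart CSV back into one PeakChart per (sample, subset)."""
    charts: dict[tuple[str, str, str], PeakChart] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            key = (row["sample"], row["sel_primary"], row["sel_secondary"])
            if key not in charts:
                charts[key] = PeakChart(*key)
            charts[key].peaks.append((float(row["size"]), float(row["height"])))
    return list(charts.values())
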