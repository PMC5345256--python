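"""Peak charts to percent methylation.

Pipeline: peaks from replicate charts of one selective subset are matched
into bins (single-linkage on size), each bin's intensities are divided by
the fully methylated SssI-reference intensity to give a signal ratio (SR),
and a Hill curve fitted against paired-digest qPCR calibration points maps
SR onto a 0-100% methylation scale:

    M(SR) = 100 * SR^h / (K^h + SR^h)

with the maximal response fixed at 100% and baseline at 0, leaving two free
parameters (h, K) for the ~dozen calibration loci one typically has.  K is
the SR of half-maximal methylation, so ``M(K) = 50`` exactly; the curve is
strictly increasing in SR and bounded in [0, 100).

SR values above 1 (sample brighter than the fully methylated reference —
pure noise) are preserved in the SR table for diagnostics and only clamped
at the percent stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fragment_db import FragmentDB, query_loci
from .simulate import PeakChart

__all__ = [
    "PeakTable",
    "HillCalibration",
    "match_peaks",
    "signal_ratio",
    "fit_hill",
    "hill_percent",
    "msre_percent",
    "charts_to_percent",
    "read_genemapper",
]

logger = logging.getLogger(__name__)


@dataclass
class PeakTable:
    """Peak bins (rows) x samples (columns) of one selective subset.

    ``table`` holds intensities in RFU with 0 for a sample absent from a
    bin; ``absent`` is the parallel boolean mask of those zeros; the row
    index is the representative size (mean of member sizes).
    """

    sel_primary: str
    sel_secondary: str
    table: pd.DataFrame
    absent: pd.DataFrame
    members: list[list[tuple[str, float, float]]] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.table.columns)


def match_peaks(charts: Sequence[PeakChart], tolerance_nt: float = 0.5) -> PeakTable:
    """Cluster peak sizes across samples into bins.

    Single linkage: pooled sizes are sorted and split wherever consecutive
    sizes are more than ``tolerance_nt`` apart.  The default 0.5 nt matches
    capillary sizing precision.  If one sample contributes two peaks to a
    bin the taller is kept (with a warning).
    """
    if not charts:
        raise ValueError("no charts to match")
    if tolerance_nt < 0:
        raise ValueError("tolerance must be >= 0")
    pairs = {(c.sel_primary, c.sel_secondary) for c in charts}
    if len(pairs) > 1:
        raise ValueError(f"charts mix selective pairs: {sorted(pairs)}")
    sel_primary, sel_secondary = next(iter(pairs))

    samples: list[str] = []
    for c in charts:
        if c.sample not in samples:
            samples.append(c.sample)
    pooled = [
        (size, height, c.sample)
        for c in charts
        for size, height in c.peaks
    ]
    pooled.sort(key=lambda t: t[0])

    bins: list[list[tuple[float, float, str]]] = []
    for peak in pooled:
        if bins and peak[0] - bins[-1][-1][0] <= tolerance_nt:
            bins[-1].append(peak)
        else:
            bins.append([peak])

    reps: list[float] = []
    rows: list[dict[str, float]] = []
    members: list[list[tuple[str, float, float]]] = []
    for members_in_bin in bins:
        reps.append(float(np.mean([p[0] for p in members_in_bin])))
        row: dict[str, float] = {}
        for size, height, sample in members_in_bin:
            if sample in row:
                logger.warning(
                    "sample %s contributes two peaks to bin at %.2f nt; "
                    "keeping the taller", sample, reps[-1],
                )
                row[sample] = max(row[sample], height)
            else:
                row[sample] = height
        rows.append(row)
        members.append([(s, sz, h) for sz, h, s in members_in_bin])

    table = pd.DataFrame(rows, index=reps, columns=samples).astype(float)
    absent = table.isna()
    table = table.fillna(0.0)
    return PeakTable(sel_primary, sel_secondary, table, absent, members)


def signal_ratio(table: PeakTable, reference_sample: str) -> pd.DataFrame:
    """Per-bin SR: sample intensity over the reference intensity.

    Bins where the reference is missing or zero cannot be normalized; they
    are dropped and reported via a warning.
    """
    if reference_sample not in table.table.columns:
        raise KeyError(f"reference sample {reference_sample!r} not in table")
    ref = table.table[reference_sample]
    valid = ref > 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning(
            "%d bins dropped: reference %s intensity is 0",
            n_dropped, reference_sample,
        )
    sub = table.table.loc[valid]
    return sub.div(sub[reference_sample], axis=0)


@dataclass
class HillCalibration:
    """Fitted SR -> percent methylation mapping; M(K) = 50 by construction."""

    h: float
    K: float
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.h <= 0 or self.K <= 0:
            raise ValueError("Hill parameters h and K must be > 0")

    @property
    def rmse(self) -> float | None:
        if self.residuals is None:
            return None
        return float(np.sqrt(np.mean(self.residuals**2)))

    def percent(self, sr) -> np.ndarray | float:
        return hill_percent(self, sr)


def hill_percent(calibration: HillCalibration, sr) -> np.ndarray | float:
    """Percent methylation for SR >= 0, clamped to [0, 100]."""
    arr = np.asarray(sr, dtype=float)
    if np.any(arr < 0):
        raise ValueError("SR must be >= 0")
    with np.errstate(divide="ignore"):
        num = np.power(arr, calibration.h)
    out = 100.0 * num / (calibration.K**calibration.h + num)
    out = np.clip(out, 0.0, 100.0)
    return float(out) if np.isscalar(sr) or arr.ndim == 0 else out


def fit_hill(points: Iterable[tuple[float, float]] | pd.DataFrame) -> HillCalibration:
    """Least-squares Hill fit of (SR, percent) calibration points.

    Multi-start over h in {0.5, 1, 2, 4} with K at the median SR, keeping
    the best objective; parameters are constrained positive by optimizing
    their logs.  Requires at least 3 points with distinct SR.
    """
    if isinstance(points, pd.DataFrame):
        pts = list(zip(points.iloc[:, 0].astype(float), points.iloc[:, 1].astype(float)))
    else:
        pts = [(float(a), float(b)) for a, b in points]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 calibration points, got {len(pts)}")
    sr = np.array([p[0] for p in pts])
    pct = np.array([p[1] for p in pts])
    if np.unique(sr).size < 2:
        raise ValueError("degenerate calibration: all SR values equal")
    if np.any(sr < 0):
        raise ValueError("SR must be >= 0")

    def resid(logparams: np.ndarray) -> np.ndarray:
        h, K = np.exp(logparams)
        with np.errstate(divide="ignore"):
            num = np.power(sr, h)
        return 100.0 * num / (K**h + num) - pct

    k0 = float(np.median(sr[sr > 0])) if np.any(sr > 0) else 1.0
    best = None
    for h0 in (0.5, 1.0, 2.0, 4.0):
        sol = least_squares(
            resid, x0=np.log([h0, k0]), xtol=1e-15, ftol=1e-15, gtol=1e-15
        )
        if best is None or sol.cost < best.cost:
            best = sol
    h, K = np.exp(best.x)
    return HillCalibration(h=float(h), K=float(K), residuals=resid(best.x))


def msre_percent(copies_hpaii: float, copies_control: float) -> float:
    """Percent methylation from the paired-digest copy numbers.

    100 x (copies surviving HpaII) / (copies surviving the control digest),
    clamped to [0, 100]; a raw ratio above 1 (qPCR noise) warns.
    """
    if copies_control <= 0:
        raise ValueError("control copy number must be > 0")
    if copies_hpaii < 0:
        raise ValueError("copy numbers must be >= 0")
    ratio = copies_hpaii / copies_control
    if ratio > 1:
        logger.warning("copy-number ratio %.3f exceeds 1; clamping to 100%%", ratio)
    return float(np.clip(100.0 * ratio, 0.0, 100.0))


def charts_to_percent(
    table: PeakTable,
    reference_sample: str,
    calibration: HillCalibration,
    db: FragmentDB | None = None,
    tolerance_nt: float = 0.5,
) -> pd.DataFrame:
    """Percent-methylation matrix for every bin x sample.

    Composition of :func:`signal_ratio` and :func:`hill_percent`.  When a
    fragment database is supplied, each bin is annotated with its candidate
    loci (may be several, or none) from the size query.
    """
    sr = signal_ratio(table, reference_sample)
    pct = sr.apply(lambda col: hill_percent(calibration, col.to_numpy()), axis=0)
    pct = pd.DataFrame(pct, index=sr.index, columns=sr.columns)
    pct = pct.drop(columns=[reference_sample])
    pct.insert(0, "sel_primary", table.sel_primary)
    pct.insert(1, "sel_secondary", table.sel_secondary)
    if db is not None:
        candidates = [
            ";".join(
                f.locus_label
                for f in query_loci(
                    db, table.sel_primary, table.sel_secondary, size, tolerance_nt
                )
            )
            or "."
            for size in pct.index
        ]
        pct.insert(2, "candidate_loci", candidates)
    return pct


def read_genemapper(
    path,
    sel_primary: str,
    sel_secondary: str,
    dye: str = "B",
) -> list[PeakChart]:
    """Read a GeneMapper-style export (Sample, Dye, Size, Height columns).

    Only rows of the configured dye channel are kept (default "B", the
    6-FAM channel used for the MspI-side selective primers).  The export
    carries no selective-pair information, so the caller supplies it.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in frame.columns}
    for needed in ("sample", "dye", "size", "height"):
        if needed not in cols:
            raise ValueError(f"GeneMapper export missing column {needed!r}")
    frame = frame[frame[cols["dye"]].astype(str).str.upper().str.startswith(dye.upper())]
    frame = frame.dropna(subset=[cols["size"], cols["height"]])
    charts: dict[str, PeakChart] = {}
    for _, row in frame.iterrows():
        sample = str(row[cols["sample"]])
        chart = charts.setdefault(sample, PeakChart(sample, sel_primary, sel_secondary))
        chart.peaks.append((float(row[cols["size"]]), float(row[cols["height"]])))
    return list(charts.values())
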