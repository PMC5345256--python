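"""Virtual MSD-AFLP fragment database: digest prediction and locus queries.

The library chemistry displays genomic fragments sandwiched between a
primary restriction site (SbfI by default) and the *nearest* CCGG
(HpaII/MspI) site, and a fragment is amplified only when the CpG of that
nearest CCGG was methylated.  This module predicts, from a genome sequence
alone, every fragment the assay can display: its genomic span, its size on
the electropherogram, the two selective dinucleotides that route it into
one of the 256 selective-PCR subsets, and the single CpG whose methylation
it reports on.

Cut-coordinate convention
-------------------------
For a primary site starting at ``p`` (recognition length ``Lp``, top-strand
cut offset ``cp``) and a secondary site starting at ``s`` (length ``Ls``,
cut offset ``cs``), both 0-based:

* ``+`` fragment (CCGG 3' of the primary site):
  insert = ``[p + cp, s + cs)``
* ``-`` fragment (CCGG 5' of the primary site):
  insert = ``[s + (Ls - cs), p + (Lp - cp))``

The two formulas are mirror images: reverse-complementing the genome maps
``+`` fragments onto ``-`` fragments with identical insert lengths.  The
monitored CpG is reported 1-based as ``s + 2`` for CCGG (the internal C).

Selective dinucleotides
-----------------------
On the fragment strand (forward for ``+``, reverse complement for ``-``)
the insert begins with the primary-enzyme remnant (``GG`` for SbfI) and
ends with the secondary remnant (``C`` for CCGG).  ``sel_primary`` is the
two bases immediately 3' of the primary remnant, read on the fragment
strand; ``sel_secondary`` is the two bases immediately 5' of the secondary
remnant, read 5'->3' on the opposite strand (the strand the MspI-side
selective primer extends), i.e. the reverse complement of those two
fragment-strand bases.  This convention is fixed; the equivalent convention
used by the original locus-prediction service is not published.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .genome_io import Genome, EnzymeSpec, find_sites, get_enzyme, revcomp

__all__ = [
    "FragmentRecord",
    "FragmentDB",
    "UniquenessReport",
    "IntragenicFraction",
    "build_db",
    "selective_bases",
    "uniqueness_report",
    "query_loci",
    "intragenic_fraction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentRecord:
    """One predicted SbfI-to-nearest-CCGG fragment.

    ``cpg_pos`` is the 1-based forward-strand position of the internal C of
    the monitored CCGG; everything else is 0-based half-open.
    """

    chromosome_name: str
    orientation: str  # "+" or "-"
    insert_start: int
    insert_end: int
    display_length: int
    sel_primary: str
    sel_secondary: str
    cpg_pos: int

    @property
    def insert_length(self) -> int:
        return self.insert_end - self.insert_start

    @property
    def subset(self) -> tuple[str, str]:
        return (self.sel_primary, self.sel_secondary)

    @property
    def cpg_key(self) -> tuple[str, int]:
        """(chromosome, 1-based CpG position) key used by methylation profiles."""
        return (self.chromosome_name, self.cpg_pos)

    @property
    def locus_label(self) -> str:
        """User-facing 1-based locus report, e.g. ``chr17:35946553``."""
        return f"{self.chromosome_name}:{self.cpg_pos}"


@dataclass
class FragmentDB:
    """The fragment database plus the parameters that produced it."""

    genome_label: str
    primary: str
    secondary: str
    display_offset: int
    size_range: tuple[int, int]
    records: list[FragmentRecord]
    n_before_size_filter: int = 0

    def __post_init__(self) -> None:
        self.records = sorted(
            self.records,
            key=lambda r: (r.chromosome_name, r.insert_start, r.orientation),
        )
        seen = set()
        for r in self.records:
            key = (r.chromosome_name, r.insert_start, r.orientation)
            if key in seen:
                raise ValueError(f"duplicate fragment record at {key}")
            seen.add(key)
        self._subsets: dict[tuple[str, str], list[FragmentRecord]] = {}
        for r in self.records:
            self._subsets.setdefault(r.subset, []).append(r)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, sel_primary: str, sel_secondary: str) -> list[FragmentRecord]:
        return self._subsets.get((sel_primary, sel_secondary), [])

    @property
    def subsets(self) -> dict[tuple[str, str], list[FragmentRecord]]:
        return self._subsets

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """TSV with ``# key=value`` metadata header lines."""
        with open(path, "w") as fh:
            fh.write(f"# genome_label={self.genome_label}\n")
            fh.write(f"# primary={self.primary}\n")
            fh.write(f"# secondary={self.secondary}\n")
            fh.write(f"# display_offset={self.display_offset}\n")
            fh.write(f"# size_range={self.size_range[0]},{self.size_range[1]}\n")
            fh.write(f"# n_before_size_filter={self.n_before_size_filter}\n")
            fh.write(
                "chromosome\torientation\tinsert_start\tinsert_end\t"
                "display_length\tsel_primary\tsel_secondary\tcpg_pos\n"
            )
            for r in self.records:
                fh.write(
                    f"{r.chromosome_name}\t{r.orientation}\t{r.insert_start}\t"
                    f"{r.insert_end}\t{r.display_length}\t{r.sel_primary}\t"
                    f"{r.sel_secondary}\t{r.cpg_pos}\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "FragmentDB":
        meta: dict[str, str] = {}
        records: list[FragmentRecord] = []
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value.strip()
                    continue
                if not header_seen:
                    header_seen = True
                    continue
                if not line:
                    continue
                c, o, a, b, d, sp, ss, cp = line.split("\t")
                records.append(
                    FragmentRecord(c, o, int(a), int(b), int(d), sp, ss, int(cp))
                )
        lo, hi = meta.get("size_range", "50,500").split(",")
        return cls(
            genome_label=meta.get("genome_label", "unknown"),
            primary=meta.get("primary", "SbfI"),
            secondary=meta.get("secondary", "HpaII"),
            display_offset=int(meta.get("display_offset", 0)),
            size_range=(int(lo), int(hi)),
            records=records,
            n_before_size_filter=int(meta.get("n_before_size_filter", 0)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": [r.chromosome_name for r in self.records],
                "orientation": [r.orientation for r in self.records],
                "insert_start": [r.insert_start for r in self.records],
                "insert_end": [r.insert_end for r in self.records],
                "display_length": [r.display_length for r in self.records],
                "sel_primary": [r.sel_primary for r in self.records],
                "sel_secondary": [r.sel_secondary for r in self.records],
                "cpg_pos": [r.cpg_pos for r in self.records],
            }
        )


def selective_bases(
    fragment_seq: str,
    primary: EnzymeSpec,
    secondary: EnzymeSpec,
) -> tuple[str, str]:
    """Selective dinucleotides from a fragment-strand insert sequence.

    ``fragment_seq`` is the insert read 5'->3' on the fragment strand (the
    forward strand for ``+`` fragments, the reverse complement for ``-``
    fragments); it begins with the primary-enzyme remnant and ends with the
    secondary remnant.  Raises ``ValueError`` if the insert is too short to
    hold both dinucleotides.
    """
    r_p = primary.size - primary.top_cut_offset
    r_s = secondary.top_cut_offset
    if len(fragment_seq) < max(r_p + 2, r_s + 2):
        raise ValueError(
            f"insert of length {len(fragment_seq)} too short for selective "
            f"dinucleotides (needs >= {max(r_p + 2, r_s + 2)})"
        )
    sel_primary = fragment_seq[r_p : r_p + 2]
    sel_secondary = revcomp(fragment_seq[len(fragment_seq) - r_s - 2 : len(fragment_seq) - r_s])
    return sel_primary, sel_secondary


def build_db(
    genome: Genome,
    primary_enzyme: str | EnzymeSpec = "SbfI",
    secondary_enzyme: str | EnzymeSpec = "HpaII",
    display_offset: int = 0,
    size_range: tuple[int, int] = (50, 500),
    genome_label: str = "genome",
) -> FragmentDB:
    """Predict every displayable fragment of ``genome``.

    For each primary site, up to two fragments are emitted — one walking
    toward increasing coordinates (``+``) and one toward decreasing (``-``)
    to the nearest secondary site.  A direction yields no fragment when no
    secondary cut lies between the primary cut and the neighbouring primary
    cut (or chromosome end), when the display length falls outside
    ``size_range``, or when the selective bases contain N or the insert is
    too short to carry them (logged, not fatal).

    ``display_offset`` is added to the genomic insert length to give the
    electrophoresed size; it absorbs the constant adaptor/primer length and
    defaults to 0 so sizes stay interpretable as genomic lengths.
    """
    p = primary_enzyme if isinstance(primary_enzyme, EnzymeSpec) else get_enzyme(primary_enzyme)
    s = secondary_enzyme if isinstance(secondary_enzyme, EnzymeSpec) else get_enzyme(secondary_enzyme)
    if size_range[0] < 1 or size_range[1] < size_range[0]:
        raise ValueError(f"invalid size_range {size_range}")

    p_sites = find_sites(genome, p)
    s_sites = find_sites(genome, s)
    p_by_chrom: dict[str, list[int]] = {}
    s_by_chrom: dict[str, list[int]] = {}
    for h in p_sites:
        p_by_chrom.setdefault(h.chromosome_name, []).append(h.site_start)
    for h in s_sites:
        s_by_chrom.setdefault(h.chromosome_name, []).append(h.site_start)

    cp, cs = p.top_cut_offset, s.top_cut_offset
    Lp, Ls = p.size, s.size
    records: list[FragmentRecord] = []
    n_unfiltered = 0

    for chrom, seq in genome.items():
        ps = p_by_chrom.get(chrom, [])
        ss_starts = s_by_chrom.get(chrom, [])
        if not ps or not ss_starts:
            continue
        plus_cuts = [x + cs for x in ss_starts]          # secondary top cuts
        minus_cuts = [x + (Ls - cs) for x in ss_starts]  # secondary bottom cuts

        for i, pstart in enumerate(ps):
            prev_p = ps[i - 1] if i > 0 else None
            next_p = ps[i + 1] if i + 1 < len(ps) else None

            # "+" direction: smallest secondary cut strictly right of p cut
            p_cut = pstart + cp
            j = bisect.bisect_right(plus_cuts, p_cut)
            if j < len(plus_cuts):
                s_start = ss_starts[j]
                s_cut = plus_cuts[j]
                if next_p is None or s_cut <= next_p + cp:
                    rec = _make_record(
                        seq, chrom, "+", p_cut, s_cut, s_start, p, s,
                        display_offset,
                    )
                    if rec is not None:
                        n_unfiltered += 1
                        if size_range[0] <= rec.display_length <= size_range[1]:
                            records.append(rec)

            # "-" direction: largest secondary bottom cut strictly left of
            # the primary bottom cut
            p_cut_b = pstart + (Lp - cp)
            j = bisect.bisect_left(minus_cuts, p_cut_b) - 1
            if j >= 0:
                s_start = ss_starts[j]
                s_cut_b = minus_cuts[j]
                if prev_p is None or s_cut_b >= prev_p + (Lp - cp):
                    rec = _make_record(
                        seq, chrom, "-", s_cut_b, p_cut_b, s_start, p, s,
                        display_offset,
                    )
                    if rec is not None:
                        n_unfiltered += 1
                        if size_range[0] <= rec.display_length <= size_range[1]:
                            records.append(rec)

    db = FragmentDB(
        genome_label=genome_label,
        primary=p.name,
        secondary=s.name,
        display_offset=display_offset,
        size_range=size_range,
        records=records,
        n_before_size_filter=n_unfiltered,
    )
    return db


def _make_record(
    seq: str,
    chrom: str,
    orientation: str,
    start: int,
    end: int,
    s_start: int,
    primary: EnzymeSpec,
    secondary: EnzymeSpec,
    display_offset: int,
) -> FragmentRecord | None:
    if end <= start:
        return None
    insert = seq[start:end]
    frag_seq = insert if orientation == "+" else revcomp(insert)
    try:
        sel_p, sel_s = selective_bases(frag_seq, primary, secondary)
    except ValueError:
        logger.warning(
            "%s:%d-%d(%s): insert too short for selective bases; excluded",
            chrom, start, end, orientation,
        )
        return None
    if "N" in sel_p or "N" in sel_s:
        logger.warning(
            "%s:%d-%d(%s): selective bases contain N; excluded",
            chrom, start, end, orientation,
        )
        return None
    block = secondary.blocking_cpg_offset
    cpg_offset = 1 if block is None else block  # internal C of CCGG
    return FragmentRecord(
        chromosome_name=chrom,
        orientation=orientation,
        insert_start=start,
        insert_end=end,
        display_length=(end - start) + display_offset,
        sel_primary=sel_p,
        sel_secondary=sel_s,
        cpg_pos=s_start + cpg_offset + 1,  # 1-based
    )


@dataclass
class UniquenessReport:
    """Size-uniqueness (single peak) statistics per selective subset."""

    total_fragments: int
    per_subset: pd.DataFrame  # index (sel_primary, sel_secondary)
    n_single_peak: int

    @property
    def fraction(self) -> float:
        return self.n_single_peak / self.total_fragments


def uniqueness_report(db: FragmentDB) -> UniquenessReport:
    """How many fragments display a single, unambiguous peak.

    Within each selective subset — one subset is one electropherogram — a
    fragment is "single peak" iff no other fragment of the subset shares
    its integer display length.  Co-migration across different subsets is
    irrelevant: those fragments are never in the same run.
    """
    if not db.records:
        raise ValueError("empty fragment database")
    rows = []
    total_single = 0
    for (sp, ss), frags in sorted(db.subsets.items()):
        counts: dict[int, int] = {}
        for f in frags:
            counts[f.display_length] = counts.get(f.display_length, 0) + 1
        n_single = sum(1 for f in frags if counts[f.display_length] == 1)
        total_single += n_single
        rows.append((sp, ss, len(frags), n_single))
    frame = pd.DataFrame(
        rows, columns=["sel_primary", "sel_secondary", "n_fragments", "n_single_peak"]
    ).set_index(["sel_primary", "sel_secondary"])
    return UniquenessReport(
        total_fragments=len(db.records),
        per_subset=frame,
        n_single_peak=total_single,
    )


def query_loci(
    db: FragmentDB,
    sel_primary: str,
    sel_secondary: str,
    observed_size: float,
    tolerance: float = 0.5,
) -> list[FragmentRecord]:
    """Candidate loci for an observed peak.

    Returns every fragment of the selective subset whose display length is
    within ``tolerance`` nt of ``observed_size``, best size match first
    (ties by genomic position).  An empty list means no candidate; more
    than one entry is the false-extra-locus situation inherent to sizing
    degeneracy.
    """
    for sel in (sel_primary, sel_secondary):
        if len(sel) != 2 or set(sel) - set("ACGT"):
            raise ValueError(f"invalid selective dinucleotide {sel!r}")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    hits = [
        f
        for f in db.subset(sel_primary, sel_secondary)
        if abs(f.display_length - observed_size) <= tolerance
    ]
    hits.sort(
        key=lambda f: (
            abs(f.display_length - observed_size),
            f.chromosome_name,
            f.insert_start,
        )
    )
    return hits


class IntragenicFraction(NamedTuple):
    fraction: float
    n_intragenic: int
    n_total: int


def intragenic_fraction(
    db: FragmentDB, gene_intervals: dict[str, list[tuple[int, int]]]
) -> IntragenicFraction:
    """Fraction of monitored CpGs lying inside annotated gene intervals."""
    if not db.records:
        raise ValueError("empty fragment database")
    # merge overlapping/nested intervals so containment is a single bisect
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in gene_intervals.items():
        starts: list[int] = []
        ends: list[int] = []
        for start, end in sorted(ivs):
            if starts and start <= ends[-1]:
                ends[-1] = max(ends[-1], end)
            else:
                starts.append(start)
                ends.append(end)
        merged[chrom] = (starts, ends)
    n_inside = 0
    for f in db.records:
        if f.chromosome_name not in merged:
            continue
        starts, ends = merged[f.chromosome_name]
        pos0 = f.cpg_pos - 1
        j = bisect.bisect_right(starts, pos0) - 1
        if j >= 0 and pos0 < ends[j]:
            n_inside += 1
    return IntragenicFraction(n_inside / len(db.records), n_inside, len(db.records))
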