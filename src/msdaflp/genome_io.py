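"""Sequence and interval I/O plus restriction-site scanning.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open (BED-style).  1-based
positions appear only in user-facing locus reports (``Chr.17 35946553``
style) and in the ``cpg_pos`` field of fragment records, which follows the
same reporting convention.

Soft-masked (lowercase) bases are uppercased and treated as ordinary
sequence; any recognition window containing ``N`` is not a site.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import re

from Bio import SeqIO

__all__ = [
    "Genome",
    "EnzymeSpec",
    "SiteHit",
    "read_fasta",
    "find_sites",
    "count_motif",
    "read_intervals",
    "write_bed",
    "load_enzymes",
    "get_enzyme",
    "revcomp",
    "is_palindromic",
]

_ALLOWED = set("ACGTN")

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide (or IUPAC) string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_palindromic(recognition: str) -> bool:
    """True if the recognition sequence equals its own reverse complement."""
    return revcomp(recognition.upper()) == recognition.upper()


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition sequence and cut geometry.

    ``top_cut_offset`` counts bases from the recognition start to the
    top-strand cut point.  ``blocking_cpg_offset`` (methylation-sensitive
    enzymes only) is the 0-based offset, within the recognition sequence, of
    the C of the CpG whose methylation blocks cleavage.
    """

    name: str
    recognition: str
    top_cut_offset: int
    blocking_cpg_offset: int | None = None
    methylation_sensitive: bool = False

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        object.__setattr__(self, "recognition", rec)
        if not 0 <= self.top_cut_offset <= len(rec):
            raise ValueError(
                f"{self.name}: top_cut_offset {self.top_cut_offset} outside "
                f"recognition of length {len(rec)}"
            )
        off = self.blocking_cpg_offset
        if off is not None:
            if not (0 <= off < len(rec) - 1 and rec[off] == "C" and rec[off + 1] == "G"):
                raise ValueError(
                    f"{self.name}: blocking_cpg_offset {off} does not index a CpG "
                    f"within {rec}"
                )

    @property
    def size(self) -> int:
        return len(self.recognition)


@dataclass(frozen=True)
class SiteHit:
    """One forward-strand recognition-site match."""

    chromosome_name: str
    site_start: int
    cut_coord: int


class Genome:
    """Ordered collection of named uppercase nucleotide sequences."""

    def __init__(self, chroms: Mapping[str, str]):
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        cleaned: dict[str, str] = {}
        for name, seq in chroms.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if name in cleaned:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - _ALLOWED
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
            cleaned[name] = seq
        self.chroms = cleaned

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __iter__(self):
        return iter(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def items(self):
        return self.chroms.items()

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> Genome:
    """Read a (optionally gzipped) FASTA file into a :class:`Genome`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    chroms: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in chroms:
                raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
            chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(chroms)


def _recognition_regex(recognition: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported; IUPAC classes never
    # include N in genome space, so windows containing N cannot match
    parts = []
    for ch in recognition.upper():
        try:
            opts = IUPAC_CODES[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in recognition sequence")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=" + "".join(parts) + ")")


def find_sites(genome: Genome, enzyme: EnzymeSpec) -> list[SiteHit]:
    """All forward-strand recognition sites, ascending per chromosome.

    Only palindromic enzymes are supported: for those, the forward-strand
    scan also captures every double-stranded site, so a single pass
    suffices.  A non-palindromic recognition raises ``ValueError`` rather
    than silently reporting half the sites.
    """
    if not is_palindromic(enzyme.recognition):
        raise ValueError(
            f"enzyme {enzyme.name}: non-palindromic recognition "
            f"{enzyme.recognition!r} is not supported"
        )
    pattern = _recognition_regex(enzyme.recognition)
    hits: list[SiteHit] = []
    for name, seq in genome.items():
        for m in pattern.finditer(seq):
            start = m.start()
            hits.append(SiteHit(name, start, start + enzyme.top_cut_offset))
    return hits


def count_motif(genome: Genome, motif: str) -> int:
    """Exact forward-strand occurrences of ``motif`` (overlaps counted)."""
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} must be over A/C/G/T")
    pattern = re.compile("(?=" + motif + ")")
    return sum(len(pattern.findall(seq)) for seq in genome.chroms.values())


def read_intervals(
    path: str | Path,
    format: str = "bed",
    feature_type: str = "gene",
) -> dict[str, list[tuple[int, int]]]:
    """Read BED (0-based half-open) or GFF3 (1-based closed) intervals.

    GFF3 keeps only rows of the configured ``feature_type`` (default
    ``gene``).  Intervals are normalized to 0-based half-open, sorted per
    chromosome.  Malformed lines are reported with their line number.
    """
    fmt = format.lower()
    if fmt not in ("bed", "gff3", "gff"):
        raise ValueError(f"unsupported interval format: {format!r}")
    intervals: dict[str, list[tuple[int, int]]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                else:
                    if len(fields) < 5:
                        raise ValueError("fewer than 5 GFF3 columns")
                    if fields[2] != feature_type:
                        continue
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                if start < 0 or end < start:
                    raise ValueError(f"invalid span [{start}, {end})")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
            intervals.setdefault(chrom, []).append((start, end))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write records as BED6.

    Each record needs ``chromosome_name``/``chrom``, a 0-based half-open
    span (``insert_start``/``insert_end`` or ``start``/``end``), and
    optionally ``name``, ``percent_methylation`` and ``orientation``.  The
    score column carries percent methylation scaled 0-1000 when available,
    else 0.
    """
    with open(path, "w") as fh:
        for rec in records:
            chrom = getattr(rec, "chromosome_name", None) or getattr(rec, "chrom")
            start = getattr(rec, "insert_start", None)
            if start is None:
                start = rec.start
                end = rec.end
            else:
                end = rec.insert_end
            name = getattr(rec, "name", None) or getattr(rec, "locus_id", None) or "."
            pct = getattr(rec, "percent_methylation", None)
            score = 0 if pct is None else int(round(pct * 10))
            strand = getattr(rec, "orientation", None) or getattr(rec, "strand", "+")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def load_enzymes() -> dict[str, EnzymeSpec]:
    """Load the shipped plain-text enzyme table."""
    text = resources.files("msdaflp").joinpath("data/enzymes.tsv").read_text()
    enzymes: dict[str, EnzymeSpec] = {}
    header_seen = False
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        name, rec, cut, block, sensitive = line.split("\t")
        enzymes[name] = EnzymeSpec(
            name=name,
            recognition=rec,
            top_cut_offset=int(cut),
            blocking_cpg_offset=None if block == "." else int(block),
            methylation_sensitive=sensitive == "yes",
        )
    return enzymes


_ENZYMES: dict[str, EnzymeSpec] | None = None


def get_enzyme(name: str) -> EnzymeSpec:
    """Look up a shipped enzyme by name (case sensitive)."""
    global _ENZYMES
    if _ENZYMES is None:
        _ENZYMES = load_enzymes()
    try:
        return _ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; shipped: {sorted(_ENZYMES)}"
        ) from None
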