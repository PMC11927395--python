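"""Assign aligned reads at a deletion locus to DEL / NODEL groups and subsample.

A read supports the deletion (DEL) when its alignment carries a deletion
spanning exactly the variant's deleted reference interval, and supports the
reference (NODEL) when it has aligned bases across the whole interval.  Reads
that only partially overlap the window, or carry any other indel inside it,
are excluded: group purity matters more than depth for a two-group statistic.

Subsampling is strand-specific: N reads are drawn without replacement from
each of the four (strand x allele) strata, mirroring a strand-specific
sequencing depth of N (so up to 4N reads feed the group statistics per
variant).  Draws are deterministic given (seed, contig, pos), so variant order
never changes them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pysam

from .variants import DeletionVariant, FlankWindow


class Strand(str, Enum):
    FWD = "FWD"
    REV = "REV"


class Allele(str, Enum):
    DEL = "DEL"
    NODEL = "NODEL"


STRATA: tuple[tuple[Strand, Allele], ...] = (
    (Strand.FWD, Allele.DEL),
    (Strand.REV, Allele.DEL),
    (Strand.FWD, Allele.NODEL),
    (Strand.REV, Allele.NODEL),
)


@dataclass(frozen=True)
class ReadGroupAssignment:
    """One read's group label at one variant, plus its window geometry."""

    read_id: str
    strand: Strand
    allele: Allele
    #: query positions of the flank bases (window order); None where unaligned
    read_window: tuple[int | None, ...]
    #: Phred base qualities at the flank bases; NaN where unaligned/missing
    window_quals: tuple[float, ...] = ()


@dataclass
class AssignmentCounts:
    """Why overlapping reads were excluded from the two groups."""

    n_considered: int = 0
    n_assigned: int = 0
    excluded_partial: int = 0
    excluded_indel_in_window: int = 0
    excluded_mixed: int = 0
    excluded_flag: int = 0


@dataclass
class AssignmentResult:
    assignments: list[ReadGroupAssignment] = field(default_factory=list)
    counts: AssignmentCounts = field(default_factory=AssignmentCounts)

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def stratum(self, strand: Strand, allele: Allele) -> list[ReadGroupAssignment]:
        return [a for a in self.assignments if a.strand is strand and a.allele is allele]


def _iter_overlapping(af: pysam.AlignmentFile, contig: str, start: int, end: int):
    """Fetch via index when available, else stream the whole file (SAM text)."""
    try:
        yield from af.fetch(contig, start, end)
    except ValueError:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != contig:
                continue
            if read.reference_start < end and read.reference_end is not None \
                    and read.reference_end > start:
                yield read


def _walk_alignment(read: pysam.AlignedSegment, region_start: int, region_end: int):
    """Per-reference-base status inside [region_start, region_end).

    Returns (status, qpos, has_insertion_inside) where status[i] is 'M' or 'D'
    for reference position region_start+i, qpos[i] is the query index for 'M'
    bases (None for 'D'), and has_insertion_inside flags an insertion strictly
    inside the region.
    """
    n = region_end - region_start
    status: list[str | None] = [None] * n
    qpos: list[int | None] = [None] * n
    insertion_inside = False
    r = read.reference_start
    q = 0
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            for j in range(length):
                p = r + j
                if region_start <= p < region_end:
                    status[p - region_start] = "M"
                    qpos[p - region_start] = q + j
            r += length
            q += length
        elif op == 1:  # I — insertion sits between r-1 and r
            if region_start < r < region_end:
                insertion_inside = True
            q += length
        elif op in (2, 3):  # D, N
            for j in range(length):
                p = r + j
                if region_start <= p < region_end:
                    status[p - region_start] = "D"
            r += length
        elif op == 4:  # S
            q += length
        # H, P consume nothing relevant
    return status, qpos, insertion_inside


def assign_reads(
    alignments,
    variant: DeletionVariant,
    window: FlankWindow | None = None,
) -> AssignmentResult:
    """Label every fully spanning read at ``variant`` as DEL or NODEL.

    ``alignments`` is a path to a SAM/BAM or an open ``pysam.AlignmentFile``.
    Reads must span the whole window (flanks + deleted interval); duplicates,
    secondary and supplementary alignments are skipped.
    """
    window = window or variant.window
    if window is None:
        raise ValueError("variant has no flank window (truncated at contig end?)")
    region_start, region_end = window.span
    dstart, dend = variant.start, variant.end
    result = AssignmentResult()
    counts = result.counts

    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments)) if own else alignments
    try:
        for read in _iter_overlapping(af, variant.contig, region_start, region_end):
            counts.n_considered += 1
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                counts.excluded_flag += 1
                continue
            if read.reference_start > region_start or (read.reference_end or 0) < region_end:
                counts.excluded_partial += 1
                continue
            status, qpos, ins_inside = _walk_alignment(read, region_start, region_end)
            if ins_inside:
                counts.excluded_indel_in_window += 1
                continue
            flank_idx = [p - region_start for p in window.positions]
            if any(status[i] != "M" for i in flank_idx):
                counts.excluded_indel_in_window += 1
                continue
            del_status = [status[p - region_start] for p in range(dstart, dend)]
            if all(s == "D" for s in del_status):
                allele = Allele.DEL
            elif all(s == "M" for s in del_status):
                allele = Allele.NODEL
            else:
                counts.excluded_mixed += 1
                continue
            quals = read.query_qualities
            window_quals = tuple(
                float(quals[qpos[i]]) if quals is not None and qpos[i] is not None
                else float("nan")
                for i in flank_idx
            )
            result.assignments.append(
                ReadGroupAssignment(
                    read_id=read.query_name,
                    strand=Strand.REV if read.is_reverse else Strand.FWD,
                    allele=allele,
                    read_window=tuple(qpos[i] for i in flank_idx),
                    window_quals=window_quals,
                )
            )
            counts.n_assigned += 1
    finally:
        if own:
            af.close()
    return result


@dataclass(frozen=True)
class SubsampleSpec:
    """Strand-specific subsampling plan: N per (strand x allele) stratum."""

    n_per_stratum: int
    seed: int = 0
    min_per_stratum: int = 20

    def __post_init__(self) -> None:
        if self.n_per_stratum < 1:
            raise ValueError("n_per_stratum must be >= 1")


@dataclass
class SubsampleResult:
    reads: list[ReadGroupAssignment]
    stratum_counts: dict[tuple[Strand, Allele], int]
    shortfall: dict[tuple[Strand, Allele], int]
    evaluable: bool

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def variant_rng(seed: int, contig: str, pos: int) -> np.random.Generator:
    """Per-variant substream so draws do not depend on variant order."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(contig.encode()), int(pos)])
    return np.random.default_rng(ss)


def subsample_strand_specific(
    assignments,
    spec: SubsampleSpec,
    contig: str = "",
    pos: int = 0,
) -> SubsampleResult:
    """Uniformly draw min(N, available) reads from each of the four strata.

    Deterministic for a fixed (seed, contig, pos).  A stratum below
    ``spec.min_per_stratum`` marks the variant not evaluable (shortfalls are
    reported, never fatal).
    """
    pool = list(assignments)
    rng = variant_rng(spec.seed, contig, pos)
    chosen: list[ReadGroupAssignment] = []
    stratum_counts: dict[tuple[Strand, Allele], int] = {}
    shortfall: dict[tuple[Strand, Allele], int] = {}
    evaluable = True
    for strand, allele in STRATA:
        members = sorted(
            (a for a in pool if a.strand is strand and a.allele is allele),
            key=lambda a: a.read_id,
        )
        take = min(spec.n_per_stratum, len(members))
        idx = rng.choice(len(members), size=take, replace=False) if take else []
        picked = [members[i] for i in sorted(idx)]
        chosen.extend(picked)
        stratum_counts[(strand, allele)] = take
        if take < spec.n_per_stratum:
            shortfall[(strand, allele)] = spec.n_per_stratum - take
        if take < spec.min_per_stratum:
            evaluable = False
    return SubsampleResult(chosen, stratum_counts, shortfall, evaluable)
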