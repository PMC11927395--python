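"""Deletion-candidate metadata: VCF parsing, homopolymer classification, flanks.

Candidate short deletions come from a low-frequency variant caller (LoFreq-style
VCF with an allele-frequency INFO key).  Each canonical deletion record
(ALT a strict prefix of REF) is turned into a :class:`DeletionVariant` carrying
the deleted reference interval, the mutated allele frequency (MuAF), a
homopolymer classification and the flanking window used by the downstream
signal and base-quality indexes.

Coordinates: VCF input/output is 1-based; everything internal is 0-based
half-open.  For a canonical deletion anchored at 1-based position ``pos`` the
deleted reference bases occupy the 0-based interval ``[pos, pos + del_len)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pysam


class DelClass(str, Enum):
    """Deletion context class: inside a >=3-base homopolymer run, or not."""

    HOMO_DEL = "HOMO_DEL"
    OTHER_DEL = "OTHER_DEL"


class WindowTruncationError(ValueError):
    """Flanking window would extend past a contig end."""


@dataclass(frozen=True)
class FlankWindow:
    """Reference positions flanking a deleted interval (0-based, deleted bases excluded)."""

    contig: str
    left: tuple[int, ...]
    right: tuple[int, ...]
    k: int

    def __post_init__(self) -> None:
        if len(self.left) != self.k or len(self.right) != self.k:
            raise ValueError("flank window must have k positions per side")
        for side in (self.left, self.right):
            if any(b - a != 1 for a, b in zip(side, side[1:])):
                raise ValueError("flank positions must be contiguous and increasing")

    @property
    def positions(self) -> tuple[int, ...]:
        """All window positions, left then right, reference order."""
        return self.left + self.right

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval covering the window and the deleted gap."""
        return self.left[0], self.right[-1] + 1

    @property
    def n_bases(self) -> int:
        return 2 * self.k


@dataclass
class DeletionVariant:
    """One candidate deletion with coordinates, alleles, MuAF and context class."""

    contig: str
    pos: int  # 1-based VCF anchor position
    ref_allele: str
    alt_allele: str
    muaf: float
    del_class: DelClass
    window: FlankWindow | None = None

    def __post_init__(self) -> None:
        if not (len(self.ref_allele) > len(self.alt_allele) > 0):
            raise ValueError("not a canonical deletion: REF must be longer than ALT")
        if not self.ref_allele.startswith(self.alt_allele):
            raise ValueError("not a canonical deletion: ALT must be a prefix of REF")

    @property
    def del_len(self) -> int:
        return len(self.ref_allele) - len(self.alt_allele)

    @property
    def deleted_seq(self) -> str:
        return self.ref_allele[len(self.alt_allele):]

    @property
    def start(self) -> int:
        """0-based start of the deleted interval."""
        # anchor base sits at pos-1 (0-based); deleted bases follow it
        return self.pos - 1 + len(self.alt_allele)

    @property
    def end(self) -> int:
        """0-based end (exclusive) of the deleted interval."""
        return self.start + self.del_len

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class ParseSummary:
    """Counts of records seen and skipped while parsing a VCF."""

    n_records: int = 0
    n_deletions: int = 0
    skipped_snv: int = 0
    skipped_insertion: int = 0
    skipped_other: int = 0
    skipped_no_af: int = 0
    skipped_low_af: int = 0
    truncated_window: int = 0


@dataclass
class ParseResult:
    variants: list[DeletionVariant] = field(default_factory=list)
    summary: ParseSummary = field(default_factory=ParseSummary)

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def _contig_sequences(reference) -> Mapping[str, str]:
    """Accept a FASTA path, a pyfaidx.Fasta, or a plain mapping contig->sequence."""
    if isinstance(reference, (str, os.PathLike)):
        import pyfaidx

        return pyfaidx.Fasta(str(reference), as_raw=True, sequence_always_upper=True)
    return reference


def _get_seq(reference, contig: str) -> str:
    seqs = _contig_sequences(reference)
    try:
        seq = seqs[contig]
    except KeyError as exc:
        raise KeyError(f"contig {contig!r} not found in the reference") from exc
    return str(seq[:]).upper()


def homopolymer_run_length(seq: str, i: int) -> int:
    """Length of the maximal run of identical bases containing position ``i``."""
    base = seq[i]
    left = i
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = i
    n = len(seq)
    while right + 1 < n and seq[right + 1] == base:
        right += 1
    return right - left + 1


def classify_deletion(reference, contig: str, start: int, end: int) -> DelClass:
    """Classify the deleted interval ``[start, end)`` (0-based) on the reference.

    HOMO_DEL iff *every* deleted base lies inside a maximal homopolymer run of
    length >= 3, measured on the reference including the deleted bases.
    """
    seq = _get_seq(reference, contig)
    if not (0 <= start < end <= len(seq)):
        raise ValueError(
            f"deleted interval [{start}, {end}) out of bounds for contig "
            f"{contig!r} of length {len(seq)}"
        )
    return (
        DelClass.HOMO_DEL
        if all(homopolymer_run_length(seq, i) >= 3 for i in range(start, end))
        else DelClass.OTHER_DEL
    )


def flank_window(variant: DeletionVariant, k: int, contig_length: int) -> FlankWindow:
    """``k`` reference positions on each side of the deleted interval.

    Raises :class:`WindowTruncationError` when the variant sits within ``k``
    bases of a contig end; such variants become NOT_EVALUATED downstream.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    start, end = variant.start, variant.end
    if start - k < 0 or end + k > contig_length:
        raise WindowTruncationError(
            f"window of k={k} around {variant.contig}:{variant.pos} "
            f"extends past a contig end"
        )
    return FlankWindow(
        contig=variant.contig,
        left=tuple(range(start - k, start)),
        right=tuple(range(end, end + k)),
        k=k,
    )


def _record_afs(record, af_key: str, n_alts: int) -> list[float] | None:
    try:
        raw = record.info[af_key]
    except KeyError:
        return None
    if isinstance(raw, (tuple, list)):
        vals = [float(v) for v in raw]
    else:
        vals = [float(raw)]
    if len(vals) == 1 and n_alts > 1:
        vals = vals * n_alts
    return vals


def parse_deletions(
    vcf_path,
    reference,
    min_muaf: float = 0.05,
    af_key: str = "AF",
    flank_k: int = 5,
) -> ParseResult:
    """Parse canonical deletion records with MuAF >= ``min_muaf`` from a VCF.

    SNVs, insertions and non-prefix MNV records are skipped and counted in the
    summary; multi-allelic records are split per allele.  Each kept variant
    carries its homopolymer class and flanking window (``window=None`` with a
    counter bump when the window would be truncated at a contig end).
    """
    if not 0.0 <= min_muaf <= 1.0:
        raise ValueError("min_muaf must be in [0, 1]")
    seqs = _contig_sequences(reference)
    result = ParseResult()
    summary = result.summary
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for record in vcf:
            summary.n_records += 1
            if record.contig not in seqs:
                raise KeyError(
                    f"contig {record.contig!r} from the VCF is missing in the reference"
                )
            alts = record.alts or ()
            afs = _record_afs(record, af_key, len(alts))
            for i, alt in enumerate(alts):
                ref = record.ref.upper()
                alt = (alt or "").upper()
                if len(ref) == len(alt) == 1:
                    summary.skipped_snv += 1
                    continue
                if len(alt) > len(ref) and alt.startswith(ref):
                    summary.skipped_insertion += 1
                    continue
                if not (len(ref) > len(alt) >= 1 and ref.startswith(alt)):
                    summary.skipped_other += 1
                    continue
                if afs is None:
                    summary.skipped_no_af += 1
                    continue
                muaf = afs[i]
                if muaf < min_muaf:
                    summary.skipped_low_af += 1
                    continue
                seq = _get_seq(seqs, record.contig)
                variant = DeletionVariant(
                    contig=record.contig,
                    pos=record.pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    muaf=muaf,
                    del_class=DelClass.OTHER_DEL,  # placeholder, set below
                )
                if variant.deleted_seq != seq[variant.start:variant.end]:
                    raise ValueError(
                        f"REF allele at {record.contig}:{record.pos} does not match "
                        f"the reference sequence"
                    )
                variant.del_class = classify_deletion(
                    seqs, record.contig, variant.start, variant.end
                )
                try:
                    variant.window = flank_window(variant, flank_k, len(seq))
                except WindowTruncationError:
                    summary.truncated_window += 1
                    variant.window = None
                result.variants.append(variant)
                summary.n_deletions += 1
    return result


def metadata_table(variants: Iterable[DeletionVariant]):
    """Variant-metadata table (one row per deletion), the metadata-module output."""
    import pandas as pd

    rows = []
    for v in variants:
        rows.append(
            {
                "contig": v.contig,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "deleted_seq": v.deleted_seq,
                "del_len": v.del_len,
                "muaf": v.muaf,
                "del_class": v.del_class.value,
                "window_start": v.window.span[0] + 1 if v.window else None,
                "window_end": v.window.span[1] if v.window else None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt", "deleted_seq", "del_len",
            "muaf", "del_class", "window_start", "window_end",
        ],
    )
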