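"""Self-contained synthetic inputs: reference, reads, signals, qualities, truth.

The generator embodies the mechanism the filter exploits.  At a **genuine
(TP) deletion**, reads carrying the deletion really lack the deleted base's
signal segment and their flanking current levels shift by ``tp_signal_shift``
relative to reads without the deletion, so the two groups separate.  At an
**artificial (FP) deletion**, the basecalls contain the deletion but the
current signal is drawn from the same template as the non-deleted reads
(near-zero group contrast), and the flanking base qualities of the
deletion-carrying reads are depressed by ``q_depression`` Phred units —
matching the empirical signatures of basecall-induced deletions.

Defaults mirror the study conditions the filter was calibrated under:
strand-specific depth 100x, MuAF 0.2 (mutant:wild-type mixes between 1:9 and
1:1), ~10 current samples per base (≈400 bases/s at a 4 kHz sampler), deletion
lengths 1–3 nt split evenly between homopolymeric (run >= 3) and
non-homopolymeric contexts.

Two granularities are provided: :func:`write_fixture_bundle` emits real files
(FASTA / SAM / VCF / signal TSV / truth TSV) for end-to-end runs, and
:func:`generate_cohort` builds per-variant binned signal pools directly for
statistics-level experiments (null calibration, depth sweeps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reads import Allele, Strand
from .signals import SignalStore, bin_normalize, save_signal_store
from .variants import DelClass

BASES = "ACGT"

#: Per-base mean current levels (normalized current units); spread is large
#: relative to the default noise so base identity structures the squiggle.
DEFAULT_LEVEL_MODEL: dict[str, float] = {"A": 80.0, "C": 95.0, "G": 110.0, "T": 125.0}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_variants: int = 20
    frac_homo: float = 0.5
    depth_per_stratum: int = 100
    muaf: float = 0.2
    samples_per_base: int = 10
    level_model: tuple[tuple[str, float], ...] = tuple(DEFAULT_LEVEL_MODEL.items())
    noise_sd: float = 2.0
    fp_fraction: float = 0.5
    tp_signal_shift: float = 6.0  # = 3 x noise_sd
    q_depression: float = 6.0
    q_baseline: float = 25.0
    q_sd: float = 3.0
    seed: int = 0
    contig: str = "synth1"
    spacing: int = 25  # filler bases between loci (>= any window half-width)
    read_flank: int = 15  # reference bases a read covers on each side of its locus

    def __post_init__(self) -> None:
        for name in ("frac_homo", "muaf", "fp_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_variants < 1 or self.depth_per_stratum < 1:
            raise ValueError("n_variants and depth_per_stratum must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.spacing < 2:
            raise ValueError("spacing too small to separate loci")

    @property
    def levels(self) -> dict[str, float]:
        return dict(self.level_model)

    def with_(self, **kw) -> "FixtureSpec":
        return replace(self, **kw)


@dataclass
class LocusPlan:
    """One planned deletion locus on the synthetic reference."""

    start: int  # 0-based first deleted base
    end: int  # 0-based, exclusive
    del_len: int
    homo: bool
    truth: str  # "TP" or "FP"

    @property
    def pos(self) -> int:
        """1-based VCF anchor position (base before the deleted interval)."""
        return self.start  # 0-based anchor = start-1 -> 1-based = start


@dataclass
class ReferencePlan:
    contig: str
    sequence: str
    loci: list[LocusPlan]


def _filler(rng: np.random.Generator, n: int, prev: str) -> str:
    """Random bases that never create a homopolymer run of 3 with context."""
    out: list[str] = []
    tail2 = prev[-2:]
    for _ in range(n):
        banned = set()
        if len(tail2) == 2 and tail2[0] == tail2[1]:
            banned.add(tail2[0])
        choices = [b for b in BASES if b not in banned]
        b = choices[rng.integers(len(choices))]
        out.append(b)
        tail2 = (tail2 + b)[-2:]
    return "".join(out)


def generate_reference(spec: FixtureSpec, rng: np.random.Generator | None = None) -> ReferencePlan:
    """Synthetic contig with ``n_variants`` planned deletion loci.

    Homopolymeric loci place the deleted bases strictly inside a run of
    ``del_len + 2`` identical bases (so every deleted base sits in a run
    >= 3); other loci alternate two bases so no deleted base's run reaches 3.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_variants
    n_homo = int(round(spec.frac_homo * n))
    n_fp = int(round(spec.fp_fraction * n))
    homo_flags = np.zeros(n, dtype=bool)
    homo_flags[rng.permutation(n)[:n_homo]] = True
    fp_flags = np.zeros(n, dtype=bool)
    fp_flags[rng.permutation(n)[:n_fp]] = True

    seq = ""
    loci: list[LocusPlan] = []
    margin = spec.spacing + spec.read_flank
    for i in range(n):
        filler = _filler(rng, margin, seq[-2:] if seq else "")
        seq += filler
        del_len = int(rng.choice([1, 2, 3], p=[0.6, 0.25, 0.15]))
        if homo_flags[i]:
            prev = seq[-1]
            b = [x for x in BASES if x != prev][rng.integers(3)]
            run_len = del_len + 2
            run_start = len(seq)
            seq += b * run_len
            start = run_start + 1
            end = start + del_len
            # next base must break the run
            nxt = [x for x in BASES if x != b][rng.integers(3)]
            seq += nxt
        else:
            prev = seq[-1]
            c1 = [x for x in BASES if x != prev][rng.integers(3)]
            c2 = [x for x in BASES if x != c1][rng.integers(3)]
            deleted = "".join(c1 if j % 2 == 0 else c2 for j in range(del_len))
            start = len(seq)
            seq += deleted
            end = len(seq)
            nxt = [x for x in BASES if x != deleted[-1]][rng.integers(3)]
            seq += nxt
        loci.append(
            LocusPlan(start=start, end=end, del_len=del_len,
                      homo=bool(homo_flags[i]),
                      truth="FP" if fp_flags[i] else "TP")
        )
    seq += _filler(rng, margin, seq[-2:])
    return ReferencePlan(contig=spec.contig, sequence=seq, loci=loci)


@dataclass
class SimRead:
    """One simulated aligned read (SAM fields precomputed)."""

    read_id: str
    ref_start: int  # 0-based
    cigar: str
    seq: str
    quals: list[int]
    strand: Strand
    allele: Allele
    locus_idx: int


@dataclass
class SimulatedDataset:
    spec: FixtureSpec
    reference: ReferencePlan
    reads: list[SimRead]
    store: SignalStore
    truth: pd.DataFrame


def _phred(rng, n, mean, sd):
    return np.clip(np.rint(rng.normal(mean, sd, size=n)), 2, 40).astype(int)


def generate_reads_and_signals(
    spec: FixtureSpec, reference: ReferencePlan, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Simulate reads, per-base squiggle segments and the truth table.

    Per locus and strand, ``round(depth_per_stratum / muaf)`` reads are drawn,
    each carrying the deletion with probability ``muaf`` (so the expected
    number of deletion reads per stratum equals the target strand depth).
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    levels = spec.levels
    seq = reference.sequence
    store = SignalStore()
    reads: list[SimRead] = []
    truth_rows = []
    for li, locus in enumerate(reference.loci):
        n_per_strand = max(1, int(round(spec.depth_per_stratum / spec.muaf)))
        n_del_total = 0
        n_total = 0
        for strand in (Strand.FWD, Strand.REV):
            is_del = rng.random(n_per_strand) < spec.muaf
            for j in range(n_per_strand):
                rstart = locus.start - spec.read_flank - int(rng.integers(0, 5))
                rend = locus.end + spec.read_flank + int(rng.integers(0, 5))
                rstart = max(0, rstart)
                rend = min(len(seq), rend)
                allele = Allele.DEL if is_del[j] else Allele.NODEL
                read_id = f"v{li:03d}_{strand.value.lower()}_{j:04d}"
                if allele is Allele.DEL:
                    covered = list(range(rstart, locus.start)) + list(range(locus.end, rend))
                    cigar = (
                        f"{locus.start - rstart}M{locus.del_len}D{rend - locus.end}M"
                    )
                else:
                    covered = list(range(rstart, rend))
                    cigar = f"{rend - rstart}M"
                read_seq = "".join(seq[p] for p in covered)
                quals = _phred(rng, len(covered), spec.q_baseline, spec.q_sd)
                if allele is Allele.DEL and locus.truth == "FP":
                    # basecall-artifact reads: depressed qualities around the call
                    for idx, p in enumerate(covered):
                        if locus.start - 5 <= p < locus.end + 5:
                            quals[idx] = max(2, quals[idx] - int(round(spec.q_depression)))
                shift = (
                    spec.tp_signal_shift
                    if (allele is Allele.DEL and locus.truth == "TP")
                    else 0.0
                )
                current: list[np.ndarray] = []
                bounds: dict[int, tuple[int, int]] = {}
                offset = 0
                for p in covered:
                    dwell = max(3, int(rng.poisson(spec.samples_per_base)))
                    seg = rng.normal(levels[seq[p]] + shift, spec.noise_sd, size=dwell)
                    current.append(seg)
                    bounds[p] = (offset, offset + dwell)
                    offset += dwell
                store.add_read(read_id, np.concatenate(current), bounds)
                reads.append(
                    SimRead(read_id, rstart, cigar, read_seq, list(quals),
                            strand, allele, li)
                )
                n_total += 1
                n_del_total += int(allele is Allele.DEL)
        anchor = locus.start - 1
        truth_rows.append(
            {
                "contig": reference.contig,
                "pos": locus.pos,
                "ref": seq[anchor:locus.end],
                "alt": seq[anchor],
                "del_len": locus.del_len,
                "del_class": (DelClass.HOMO_DEL if locus.homo else DelClass.OTHER_DEL).value,
                "truth": locus.truth,
                "designed_muaf": spec.muaf,
                "observed_muaf": n_del_total / n_total,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(spec, reference, reads, store, truth)


def _write_fasta(path, contig: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def _write_sam(path, dataset: SimulatedDataset) -> None:
    ref = dataset.reference
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{ref.contig}\tLN:{len(ref.sequence)}\n")
        for read in sorted(dataset.reads, key=lambda r: (r.ref_start, r.read_id)):
            flag = 16 if read.strand is Strand.REV else 0
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(
                f"{read.read_id}\t{flag}\t{ref.contig}\t{read.ref_start + 1}\t60\t"
                f"{read.cigar}\t*\t0\t0\t{read.seq}\t{qual}\n"
            )


def _write_vcf(path, dataset: SimulatedDataset) -> None:
    ref = dataset.reference
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write(f"##contig=<ID={ref.contig},length={len(ref.sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in dataset.truth.iterrows():
            fh.write(
                f"{row['contig']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"100\tPASS\tAF={row['observed_muaf']:.4f}\n"
            )


def write_fixture_bundle(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Emit FASTA + SAM + VCF + signal TSV + truth TSV; byte-stable per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(spec)
    dataset = generate_reads_and_signals(spec, reference)
    paths = {
        "reference": out / "ref.fa",
        "alignments": out / "reads.sam",
        "vcf": out / "variants.vcf",
        "signals": out / "signals.tsv",
        "truth": out / "truth.tsv",
    }
    _write_fasta(paths["reference"], reference.contig, reference.sequence)
    _write_sam(paths["alignments"], dataset)
    _write_vcf(paths["vcf"], dataset)
    save_signal_store(dataset.store, paths["signals"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.4f")
    return paths


# ---------------------------------------------------------------------------
# statistics-level cohorts (no file I/O): per-variant binned signal pools
# ---------------------------------------------------------------------------

@dataclass
class CohortVariant:
    """Pools of pre-binned signal rows and per-read mean window qualities."""

    truth: str  # "TP" or "FP"
    del_class: DelClass
    rows: dict[tuple[Strand, Allele], np.ndarray]  # (pool, bins)
    quals: dict[tuple[Strand, Allele], np.ndarray]  # (pool,)


def generate_cohort(
    spec: FixtureSpec,
    pool_per_stratum: int | None = None,
    window_bases: int = 10,
    n_bins: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[CohortVariant]:
    """Per-variant stratum pools of length-normalized window signals.

    Equivalent to extracting and bin-normalizing the flanking squiggles of
    ``pool_per_stratum`` reads per (strand x allele) stratum at every locus,
    without materializing files.  TP loci shift the DEL rows' levels by
    ``tp_signal_shift``; FP loci draw DEL rows from the NODEL template and
    depress DEL-read qualities by ``q_depression``.
    """
    rng = rng or np.random.default_rng(spec.seed)
    pool = pool_per_stratum or spec.depth_per_stratum
    bins = n_bins or 10 * window_bases
    levels = np.array(list(spec.levels.values()))
    n_homo = int(round(spec.frac_homo * spec.n_variants))
    n_fp = int(round(spec.fp_fraction * spec.n_variants))
    homo_flags = np.zeros(spec.n_variants, dtype=bool)
    homo_flags[rng.permutation(spec.n_variants)[:n_homo]] = True
    fp_flags = np.zeros(spec.n_variants, dtype=bool)
    fp_flags[rng.permutation(spec.n_variants)[:n_fp]] = True

    cohort: list[CohortVariant] = []
    for v in range(spec.n_variants):
        base_levels = levels[rng.integers(0, len(levels), size=window_bases)]
        rows: dict[tuple[Strand, Allele], np.ndarray] = {}
        quals: dict[tuple[Strand, Allele], np.ndarray] = {}
        truth = "FP" if fp_flags[v] else "TP"
        for strand in (Strand.FWD, Strand.REV):
            for allele in (Allele.DEL, Allele.NODEL):
                shift = (
                    spec.tp_signal_shift
                    if (allele is Allele.DEL and truth == "TP")
                    else 0.0
                )
                mat = np.empty((pool, bins))
                for r in range(pool):
                    dwells = np.maximum(3, rng.poisson(spec.samples_per_base, window_bases))
                    sig = np.concatenate(
                        [
                            rng.normal(base_levels[b] + shift, spec.noise_sd, size=dwells[b])
                            for b in range(window_bases)
                        ]
                    )
                    mat[r] = bin_normalize(sig, bins)
                rows[(strand, allele)] = mat
                q_mean = spec.q_baseline - (
                    spec.q_depression if (allele is Allele.DEL and truth == "FP") else 0.0
                )
                quals[(strand, allele)] = (
                    rng.normal(q_mean, spec.q_sd / np.sqrt(window_bases), size=pool)
                )
        cohort.append(
            CohortVariant(
                truth=truth,
                del_class=DelClass.HOMO_DEL if homo_flags[v] else DelClass.OTHER_DEL,
                rows=rows,
                quals=quals,
            )
        )
    return cohort
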