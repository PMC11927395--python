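"""Per-read current-signal store, flank extraction and length normalization.

A nanopore read's squiggle is an ordered vector of current measurements; a
resquiggle step assigns a contiguous slice of it to every reference-aligned
base.  :class:`SignalStore` holds that per-read, per-reference-base
segmentation.  The portable on-disk form is a plain TSV (one line per read and
reference base, current values comma-separated); an adapter reads
Tombo-resquiggled single-read fast5 directories into the same store.

Because translocation speed varies, equal base counts yield unequal signal
lengths.  ``bin_normalize`` equalizes lengths by averaging measurements within
B equal-occupancy bins, so reads become rows of a reads x bins matrix on which
the two-group statistics operate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reads import Allele, ReadGroupAssignment
from .variants import FlankWindow

#: MinION digitization rate (samples per second).
DEFAULT_SAMPLE_RATE = 4000.0


class MissingSegmentError(KeyError):
    """A read lacks a signal segment for a requested reference base."""


class NotEvaluatedError(RuntimeError):
    """A variant cannot be scored (e.g. one group lost all its reads)."""


@dataclass
class SignalStore:
    """Mapping read_id -> (current vector, per-reference-base segment bounds)."""

    signals: dict[str, np.ndarray] = field(default_factory=dict)
    bounds: dict[str, dict[int, tuple[int, int]]] = field(default_factory=dict)

    def add_read(
        self,
        read_id: str,
        current: Sequence[float],
        base_bounds: dict[int, tuple[int, int]],
    ) -> None:
        arr = np.asarray(current, dtype=float)
        last = 0
        for refpos in sorted(base_bounds):
            s, e = base_bounds[refpos]
            if not (0 <= s < e <= arr.size) or s < last:
                raise ValueError(
                    f"segment bounds for read {read_id!r} base {refpos} are "
                    f"out of order or outside the signal"
                )
            last = e
        self.signals[read_id] = arr
        self.bounds[read_id] = dict(base_bounds)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.signals

    def __len__(self) -> int:
        return len(self.signals)

    def segment(self, read_id: str, refpos: int) -> np.ndarray:
        """Current measurements assigned to one reference base of one read."""
        try:
            s, e = self.bounds[read_id][refpos]
        except KeyError:
            raise MissingSegmentError(
                f"read {read_id!r} has no segment at reference position {refpos}"
            ) from None
        return self.signals[read_id][s:e]

    def covered_positions(self, read_id: str) -> list[int]:
        return sorted(self.bounds.get(read_id, ()))


def save_signal_store(store: SignalStore, path) -> None:
    """Write the portable TSV: read_id <TAB> 0-based refpos <TAB> v1,v2,..."""
    with open(path, "w") as fh:
        fh.write("#read_id\trefpos\tcurrent\n")
        for read_id in sorted(store.signals):
            for refpos in sorted(store.bounds[read_id]):
                seg = store.segment(read_id, refpos)
                fh.write(
                    f"{read_id}\t{refpos}\t"
                    + ",".join(format(v, ".4f") for v in seg)
                    + "\n"
                )


def load_signal_store(path) -> SignalStore:
    """Read the portable TSV written by :func:`save_signal_store`."""
    per_read: dict[str, list[tuple[int, np.ndarray]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            read_id, refpos, values = line.rstrip("\n").split("\t")
            seg = (
                np.array([float(v) for v in values.split(",")])
                if values
                else np.empty(0)
            )
            if seg.size == 0:
                raise ValueError(f"empty segment for read {read_id!r} at {refpos}")
            per_read.setdefault(read_id, []).append((int(refpos), seg))
    store = SignalStore()
    for read_id, segs in per_read.items():
        segs.sort(key=lambda t: t[0])
        current = np.concatenate([s for _, s in segs])
        bounds: dict[int, tuple[int, int]] = {}
        offset = 0
        for refpos, s in segs:
            bounds[refpos] = (offset, offset + s.size)
            offset += s.size
        store.add_read(read_id, current, bounds)
    return store


def load_tombo_fast5_dir(
    directory,
    corrected_group: str = "RawGenomeCorrected_000",
    basecall_subgroup: str = "BaseCalled_template",
) -> SignalStore:
    """Adapter: read Tombo-resquiggled single-read fast5 files into a store.

    Uses each file's event table (per-base start/length into the raw signal)
    and its shift/scale attributes to reconstruct the normalized per-base
    segments in reference orientation.  Files without a resquiggle analysis
    group are skipped.
    """
    import h5py

    store = SignalStore()
    for path in sorted(Path(directory).glob("*.fast5")):
        with h5py.File(path, "r") as f5:
            try:
                bc = f5[f"Analyses/{corrected_group}/{basecall_subgroup}"]
                events = bc["Events"][...]
                aln = bc["Alignment"]
                mapped_start = int(aln.attrs["mapped_start"])
                raw_grp = next(iter(f5["Raw/Reads"].values()))
                raw = np.asarray(raw_grp["Signal"][...], dtype=float)
                read_id = raw_grp.attrs.get("read_id", path.stem)
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
            except (KeyError, StopIteration):
                continue
            rel = int(events.attrs.get("read_start_rel_to_raw", 0)) \
                if hasattr(events, "attrs") else 0
            rel = int(bc["Events"].attrs.get("read_start_rel_to_raw", rel))
            shift = float(bc.attrs.get("shift", 0.0))
            scale = float(bc.attrs.get("scale", 1.0))
            norm = (raw - shift) / (scale if scale else 1.0)
            starts = np.asarray(events["start"], dtype=int) + rel
            lengths = np.asarray(events["length"], dtype=int)
            bounds = {
                mapped_start + i: (int(s), int(s + l))
                for i, (s, l) in enumerate(zip(starts, lengths))
            }
            store.add_read(str(read_id), norm, bounds)
    return store


def extract_flank_signal(
    store: SignalStore,
    read: ReadGroupAssignment | str,
    window: FlankWindow,
) -> np.ndarray:
    """Concatenated current of the left-flank then right-flank bases of a read.

    Flanks only — the deleted interval contributes nothing, so DEL and NODEL
    rows describe homologous sequence.  Raises :class:`MissingSegmentError`
    when the read is absent or any window base lacks a segment.
    """
    read_id = read if isinstance(read, str) else read.read_id
    if read_id not in store:
        raise MissingSegmentError(f"read {read_id!r} not present in the signal store")
    parts = [store.segment(read_id, p) for p in window.positions]
    return np.concatenate(parts)


def bin_normalize(signal: Sequence[float], n_bins: int) -> np.ndarray:
    """Length-normalize a signal to ``n_bins`` bin means.

    Bin ``i`` covers sample indexes ``[floor(i*L/B), floor((i+1)*L/B))``.  When
    L < B some slices are empty; empty bins carry the nearest preceding bin
    value forward (leading empties are back-filled from the first non-empty).
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bin an empty signal")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    L, B = x.size, n_bins
    edges = (np.arange(B + 1, dtype=np.int64) * L) // B
    counts = np.diff(edges)
    if np.all(counts > 0):  # fast path: every bin occupied (L >= B)
        return np.add.reduceat(x, edges[:-1]) / counts
    out = np.empty(B)
    out.fill(np.nan)
    for i in range(B):
        s, e = edges[i], edges[i + 1]
        if e > s:
            out[i] = x[s:e].mean()
    # carry forward, then back-fill any leading gap
    last = np.nan
    for i in range(B):
        if math.isnan(out[i]):
            out[i] = last
        else:
            last = out[i]
    first = out[~np.isnan(out)][0]
    out[np.isnan(out)] = first
    return out


def sequencing_speed(
    signal_length: int,
    n_bases: int,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> tuple[float, float]:
    """(measurements per base, bases per second) for a read fragment.

    The sampler ticks at a fixed rate, so measurements/base is inversely
    proportional to translocation speed.
    """
    if n_bases < 1:
        raise ValueError("n_bases must be >= 1")
    if signal_length < 1:
        raise ValueError("signal_length must be >= 1")
    per_base = signal_length / n_bases
    return per_base, sample_rate / per_base


@dataclass
class NormalizedSignalMatrix:
    """Reads x bins matrix of bin-mean currents with DEL/NODEL row labels."""

    values: np.ndarray
    labels: list[Allele]
    read_ids: list[str]
    bins: int
    window_bases: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.bins:
            raise ValueError("matrix shape does not match the bin count")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix rows must be finite")

    @property
    def n_del(self) -> int:
        return sum(1 for l in self.labels if l is Allele.DEL)

    @property
    def n_nodel(self) -> int:
        return sum(1 for l in self.labels if l is Allele.NODEL)

    def group(self, allele: Allele) -> np.ndarray:
        mask = np.array([l is allele for l in self.labels])
        return self.values[mask]


def build_matrix(
    store: SignalStore,
    reads: Iterable[ReadGroupAssignment],
    window: FlankWindow,
    n_bins: int,
) -> NormalizedSignalMatrix:
    """Extract + bin-normalize flank signals for a set of labeled reads.

    Rows are sorted by read_id for run-to-run stability.  Reads missing from
    the store (or missing a window segment) are dropped and counted; a label
    with zero surviving rows raises :class:`NotEvaluatedError`.
    """
    rows: list[np.ndarray] = []
    labels: list[Allele] = []
    ids: list[str] = []
    dropped = 0
    for read in sorted(reads, key=lambda r: r.read_id):
        try:
            sig = extract_flank_signal(store, read, window)
        except MissingSegmentError:
            dropped += 1
            continue
        rows.append(bin_normalize(sig, n_bins))
        labels.append(read.allele)
        ids.append(read.read_id)
    if not rows or not any(l is Allele.DEL for l in labels) \
            or not any(l is Allele.NODEL for l in labels):
        raise NotEvaluatedError(
            "a group has no surviving reads after signal extraction"
        )
    return NormalizedSignalMatrix(
        values=np.vstack(rows),
        labels=labels,
        read_ids=ids,
        bins=n_bins,
        window_bases=window.n_bases,
        n_dropped=dropped,
    )
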