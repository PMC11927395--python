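"""Two-group distance statistics on normalized signal matrices, plus the
flanking base-quality index.

Four indexes quantify how strongly the current signals of deletion-supporting
reads differ from reads without the deletion at the same locus:

* **MRPP A** — chance-corrected within-group agreement.  With Euclidean
  pairwise distances, the observed weighted within-group mean distance is
  ``delta = sum_g (n_g/N) * mean within-group distance of g``; A = 1 −
  delta_obs / delta_exp where delta_exp is the expectation of delta under
  random relabeling.  With weights n_g/N that expectation has a closed form:
  the mean of all pairwise distances (each pair is within-group with a
  probability independent of the pair, so the weighted mean is the overall
  mean).  A permutation / full-enumeration mode is kept as a cross-check.
* **ANOSIM R** — rank the pairwise distances (average ranks on ties);
  R = (mean between-group rank − mean within-group rank) / (M/2),
  M = n(n−1)/2.  Bounded in [−1, 1].
* **ADONIS pseudo-F** — distance-based one-way ANOVA:
  SS_total = (1/N) Σ_{i<j} d_ij²; SS_within = Σ_g (1/n_g) Σ_{i<j in g} d_ij²;
  F = (SS_between/(k−1)) / (SS_within/(N−k)).
* **accumulative difference** — Σ over bins of |mean DEL profile − mean NODEL
  profile|, in current units.

A genuine (true-positive) deletion changes the local squiggle, so DEL reads
separate from NODEL reads and all four indexes rise; a basecall artifact
leaves near-identical signals and the indexes sit near their null values.
The fifth index, the 10-mer mean Q score, averages Phred qualities over the
window bases of the deletion-supporting reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .reads import Allele, ReadGroupAssignment
from .signals import NormalizedSignalMatrix, NotEvaluatedError
from .variants import FlankWindow


@dataclass
class GroupComparisonResult:
    """All four signal indexes for one variant."""

    mrpp_a: float
    anosim_r: float
    adonis_f: float
    accum_diff: float
    n_del: int
    n_nodel: int
    distance_metric: str = "euclidean"


@dataclass
class QScoreIndex:
    """Mean flanking Phred quality of the deletion-supporting reads."""

    mean_q: float
    n_reads: int
    window_len: int
    per_read: tuple[float, ...] = ()


def _coerce(matrix, labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept a NormalizedSignalMatrix or (values, labels) arrays."""
    if isinstance(matrix, NormalizedSignalMatrix):
        values = matrix.values
        labs = np.array([l is Allele.DEL for l in matrix.labels])
    else:
        values = np.asarray(matrix, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        labs = np.array(
            [l is Allele.DEL if isinstance(l, Allele) else bool(l) for l in labels]
        )
    if values.shape[0] != labs.size:
        raise ValueError("one label per row required")
    return values, labs


def _check_groups(labs: np.ndarray, min_per_group: int) -> None:
    n1 = int(labs.sum())
    n0 = labs.size - n1
    if n1 < min_per_group or n0 < min_per_group:
        raise NotEvaluatedError(
            f"need >= {min_per_group} rows per group (got {n1} and {n0})"
        )


def _weighted_within_delta(dmat: np.ndarray, labs: np.ndarray) -> float:
    """delta = sum_g (n_g/N) * (mean within-group pairwise distance of g)."""
    n = labs.size
    delta = 0.0
    for flag in (True, False):
        idx = np.flatnonzero(labs == flag)
        ng = idx.size
        if ng < 2:
            continue
        sub = dmat[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(ng, k=1)].mean()
        delta += (ng / n) * mean_within
    return delta


def mrpp_a(
    matrix,
    labels=None,
    mode: str = "analytic",
    n_perm: int = 999,
    seed: int | None = None,
    metric: str = "euclidean",
) -> float:
    """MRPP statistic A with group weights n_g/N.

    ``mode='analytic'`` uses the closed-form expectation of delta under random
    relabeling (the overall mean pairwise distance); ``'permutation'`` averages
    delta over ``n_perm`` random relabelings; ``'enumerate'`` averages over all
    distinct relabelings (small N only).  Degenerate matrices with zero
    expected delta return A = 0 by convention.
    """
    values, labs = _coerce(matrix, labels)
    _check_groups(labs, 2)
    dmat = squareform(pdist(values, metric=metric))
    delta_obs = _weighted_within_delta(dmat, labs)
    n = labs.size
    if mode == "analytic":
        delta_exp = dmat[np.triu_indices(n, k=1)].mean()
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        deltas = []
        for _ in range(n_perm):
            perm = labs[rng.permutation(n)]
            deltas.append(_weighted_within_delta(dmat, perm))
        delta_exp = float(np.mean(deltas))
    elif mode == "enumerate":
        n1 = int(labs.sum())
        deltas = []
        for combo in combinations(range(n), n1):
            relab = np.zeros(n, dtype=bool)
            relab[list(combo)] = True
            deltas.append(_weighted_within_delta(dmat, relab))
        delta_exp = float(np.mean(deltas))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if delta_exp == 0.0:
        return 0.0
    return 1.0 - delta_obs / delta_exp


def mrpp_permutation_mean(
    matrix,
    labels=None,
    n_perm: int = 2000,
    seed: int | None = None,
    metric: str = "euclidean",
) -> float:
    """Mean of A over random relabelings (≈0 for exchangeable rows)."""
    values, labs = _coerce(matrix, labels)
    _check_groups(labs, 2)
    dmat = squareform(pdist(values, metric=metric))
    n = labs.size
    delta_exp = dmat[np.triu_indices(n, k=1)].mean()
    if delta_exp == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_perm):
        perm = labs[rng.permutation(n)]
        vals.append(1.0 - _weighted_within_delta(dmat, perm) / delta_exp)
    return float(np.mean(vals))


def anosim_r(matrix, labels=None, metric: str = "euclidean") -> float:
    """ANOSIM statistic R on ranked pairwise distances (average ranks on ties)."""
    values, labs = _coerce(matrix, labels)
    _check_groups(labs, 2)
    d = pdist(values, metric=metric)
    ranks = rankdata(d)
    n = labs.size
    between = np.array(
        [labs[i] != labs[j] for i, j in combinations(range(n), 2)]
    )
    m = d.size  # n(n-1)/2
    rb = ranks[between].mean()
    rw = ranks[~between].mean()
    return float((rb - rw) / (m / 2.0))


def adonis_f(matrix, labels=None, metric: str = "euclidean") -> float:
    """Distance-based one-way pseudo-F for the two groups.

    Zero within-group spread with separated groups yields +inf; all rows
    identical yields 0.
    """
    values, labs = _coerce(matrix, labels)
    _check_groups(labs, 2)
    d2 = pdist(values, metric=metric) ** 2
    n = labs.size
    k = 2
    ss_total = d2.sum() / n
    ss_within = 0.0
    for flag in (True, False):
        idx = np.flatnonzero(labs == flag)
        if idx.size < 2:
            continue
        ss_within += (pdist(values[idx], metric=metric) ** 2).sum() / idx.size
    ss_between = ss_total - ss_within
    if ss_within <= 0.0:
        return math.inf if ss_between > 1e-12 else 0.0
    return float((ss_between / (k - 1)) / (ss_within / (n - k)))


def accumulative_difference(matrix, labels=None) -> float:
    """Σ over bins of |mean DEL profile − mean NODEL profile| (current units)."""
    values, labs = _coerce(matrix, labels)
    if labs.all() or not labs.any():
        raise NotEvaluatedError("both groups must be non-empty")
    prof_del = values[labs].mean(axis=0)
    prof_nodel = values[~labs].mean(axis=0)
    return float(np.abs(prof_del - prof_nodel).sum())


def group_compare(
    matrix: NormalizedSignalMatrix,
    metric: str = "euclidean",
    mrpp_mode: str = "analytic",
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupComparisonResult:
    """All four signal indexes for one variant's matrix."""
    return GroupComparisonResult(
        mrpp_a=mrpp_a(matrix, mode=mrpp_mode, n_perm=n_perm, seed=seed, metric=metric),
        anosim_r=anosim_r(matrix, metric=metric),
        adonis_f=adonis_f(matrix, metric=metric),
        accum_diff=accumulative_difference(matrix),
        n_del=matrix.n_del,
        n_nodel=matrix.n_nodel,
        distance_metric=metric,
    )


def qscore_index(
    reads: Iterable[ReadGroupAssignment],
    window: FlankWindow,
    group: Allele = Allele.DEL,
) -> QScoreIndex:
    """Mean flanking Phred quality over the deletion-supporting reads.

    Each read contributes the mean of its qualities at the window bases
    (bases falling in a deleted/clipped part of that read are skipped);
    the index is the mean of those per-read means, in Phred units.
    """
    per_read: list[float] = []
    for read in reads:
        if read.allele is not group:
            continue
        quals = np.asarray(read.window_quals, dtype=float)
        quals = quals[np.isfinite(quals)]
        if quals.size:
            per_read.append(float(quals.mean()))
    if not per_read:
        raise NotEvaluatedError("no reads with usable base qualities in the group")
    return QScoreIndex(
        mean_q=float(np.mean(per_read)),
        n_reads=len(per_read),
        window_len=window.n_bases,
        per_read=tuple(per_read),
    )
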