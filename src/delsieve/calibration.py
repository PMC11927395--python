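"""Threshold calibration: ROC/AUC per index and depth-stratified sweeps.

All filter indexes score *low* on artificial (FP) deletions, so a candidate
threshold ``t`` flags a variant as artificial when its index value is strictly
below ``t``.  Sensitivity is the fraction of FP variants flagged and
specificity the fraction of TP variants kept.  The AUC is computed with the
rank (Mann–Whitney) formulation, with average ranks on ties; the default
threshold is the candidate cut point maximizing sensitivity + specificity
(Youden), ties broken toward higher specificity.

``depth_sweep`` repeats the whole measurement across strand-specific depths N:
for each replicate it subsamples N reads per (strand x allele) stratum from a
synthetic cohort's pools, recomputes every index per variant, and runs the ROC
across variants — reproducing the subsampling design used to pick the
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .reads import Allele, Strand
from .simulate import CohortVariant
from .stats import accumulative_difference, adonis_f, anosim_r, mrpp_a

SIGNAL_INDEXES: dict[str, Callable] = {
    "mrpp_a": mrpp_a,
    "anosim_r": anosim_r,
    "adonis_f": adonis_f,
    "accum_diff": accumulative_difference,
}
ALL_INDEXES = tuple(SIGNAL_INDEXES) + ("qscore",)

DEFAULT_DEPTH_GRID = (20, 50, 100, 200, 400, 800)


@dataclass
class ROCResult:
    auc: float
    best_threshold: float
    sensitivity_at_best: float
    specificity_at_best: float
    n_pos: int  # FP (artifact) variants — the class being detected
    n_neg: int  # TP (genuine) variants


def _as_fp_mask(labels: Sequence) -> np.ndarray:
    mask = []
    for l in labels:
        if isinstance(l, str):
            if l.upper() not in ("FP", "TP"):
                raise ValueError(f"label must be 'FP' or 'TP', got {l!r}")
            mask.append(l.upper() == "FP")
        else:
            mask.append(bool(l))
    return np.array(mask)


def roc(scores: Sequence[float], labels: Sequence, low_is_fp: bool = True) -> ROCResult:
    """ROC of an index against FP/TP truth labels.

    ``labels`` are 'FP'/'TP' strings (or truthy = FP).  With ``low_is_fp``
    (the case for every filter index) low scores indicate artifacts; passing
    ``False`` negates the scores first, so the AUC is invariant under jointly
    flipping sign and direction.
    """
    s = np.asarray(scores, dtype=float)
    is_fp = _as_fp_mask(labels)
    if s.size != is_fp.size:
        raise ValueError("scores and labels must have equal length")
    n_fp = int(is_fp.sum())
    n_tp = int(s.size - n_fp)
    if n_fp == 0 or n_tp == 0:
        raise ValueError("both FP and TP labels are required for a ROC")
    if not low_is_fp:
        s = -s
    # rank formulation: AUC = P(score_TP > score_FP) + 0.5 P(tie)
    ranks = rankdata(s)
    auc = (ranks[~is_fp].sum() - n_tp * (n_tp + 1) / 2.0) / (n_tp * n_fp)

    distinct = np.unique(s)
    candidates = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    best = None
    for t in candidates:
        flagged = s < t
        sens = flagged[is_fp].mean()
        spec = (~flagged[~is_fp]).mean()
        key = (sens + spec, spec, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t, sens, spec = best
    return ROCResult(
        auc=float(auc),
        best_threshold=float(t),
        sensitivity_at_best=float(sens),
        specificity_at_best=float(spec),
        n_pos=n_fp,
        n_neg=n_tp,
    )


def cohort_index_values(
    cohort: Iterable[CohortVariant],
    n_per_stratum: int,
    rng: np.random.Generator,
    indexes: Sequence[str] = ALL_INDEXES,
) -> pd.DataFrame:
    """Per-variant index values at one subsampled strand depth.

    For each variant, ``min(N, pool)`` rows are drawn without replacement from
    each (strand x allele) pool; the signal indexes run on the stacked matrix
    and the Q-score index averages the sampled DEL reads' qualities.
    """
    rows = []
    for vi, var in enumerate(cohort):
        picks: dict[tuple[Strand, Allele], np.ndarray] = {}
        for key, pool in var.rows.items():
            take = min(n_per_stratum, pool.shape[0])
            picks[key] = rng.choice(pool.shape[0], size=take, replace=False)
        values = np.vstack(
            [var.rows[key][picks[key]] for key in sorted(picks, key=str)]
        )
        labels = np.concatenate(
            [
                np.full(picks[key].size, key[1] is Allele.DEL)
                for key in sorted(picks, key=str)
            ]
        )
        row = {"variant": vi, "truth": var.truth, "del_class": var.del_class.value}
        for name in indexes:
            if name == "qscore":
                q = np.concatenate(
                    [
                        var.quals[key][picks[key]]
                        for key in picks
                        if key[1] is Allele.DEL
                    ]
                )
                row[name] = float(q.mean())
            else:
                row[name] = float(SIGNAL_INDEXES[name](values, labels))
        rows.append(row)
    return pd.DataFrame(rows)


def depth_sweep(
    cohort: Sequence[CohortVariant],
    depths: Sequence[int] = DEFAULT_DEPTH_GRID,
    reps: int = 10,
    seed: int = 0,
    indexes: Sequence[str] = ALL_INDEXES,
) -> pd.DataFrame:
    """AUC and best threshold per (index, strand depth, replicate).

    Deterministic for a fixed seed: each (depth, rep) cell draws from its own
    seed substream, so grid order never changes the draws.
    """
    records = []
    for n in depths:
        for rep in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(n), int(rep)])
            )
            table = cohort_index_values(cohort, n, rng, indexes)
            for name in indexes:
                res = roc(table[name].to_numpy(), table["truth"].tolist())
                records.append(
                    {
                        "index": name,
                        "n": n,
                        "rep": rep,
                        "auc": res.auc,
                        "best_threshold": res.best_threshold,
                        "sensitivity": res.sensitivity_at_best,
                        "specificity": res.specificity_at_best,
                    }
                )
    return pd.DataFrame(records)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max AUC and mean best threshold per (index, depth)."""
    g = sweep.groupby(["index", "n"])
    out = g.agg(
        auc_mean=("auc", "mean"),
        auc_min=("auc", "min"),
        auc_max=("auc", "max"),
        threshold_mean=("best_threshold", "mean"),
    ).reset_index()
    return out


def recommend_thresholds(sweep: pd.DataFrame) -> dict:
    """Table-style recommendation block (per index, at the deepest sweep N)."""
    summary = summarize_sweep(sweep)
    rec: dict[str, dict] = {}
    for name, sub in summary.groupby("index"):
        deepest = sub.loc[sub["n"].idxmax()]
        rec[str(name)] = {
            "strand_depth": int(deepest["n"]),
            "auc": round(float(deepest["auc_mean"]), 4),
            "threshold": float(deepest["threshold_mean"]),
        }
    return rec
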