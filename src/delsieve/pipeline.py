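"""End-to-end filter run: VCF + alignments + reference (+ signal store) -> decisions.

Per candidate deletion: parse and classify, assign overlapping reads to
DEL/NODEL strata, subsample to the configured strand depth, compute the index
chosen by the run-metadata selector (MRPP A on the bin-normalized flanking
squiggles, or the mean flanking Q score), and apply the strict
below-threshold rule.  Variants that cannot be scored — window truncated at a
contig end, a stratum under 20 reads, reads missing from the signal store —
come out NOT_EVALUATED rather than silently kept or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .filtering import (
    INDEX_MRPP,
    INDEX_QSCORE,
    FilterDecision,
    SelectorConfig,
    Verdict,
    decide,
    select_index,
    summarize,
    write_filtered_vcf,
)
from .reads import SubsampleSpec, assign_reads, subsample_strand_specific
from .signals import NotEvaluatedError, SignalStore, build_matrix
from .stats import group_compare, mrpp_a, qscore_index
from .variants import DeletionVariant, flank_window, parse_deletions


@dataclass
class PipelineResult:
    decisions: list[FilterDecision] = field(default_factory=list)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    summary: dict[str, int] = field(default_factory=dict)
    parse_summary: object = None


def score_variant(
    variant: DeletionVariant,
    alignments,
    config: SelectorConfig,
    signal_store: SignalStore | None = None,
    signal_flank_k: int = 5,
    qscore_flank_k: int = 5,
    n_bins: int | None = None,
    seed: int = 0,
    mrpp_mode: str = "analytic",
    collect_all: bool = False,
) -> tuple[FilterDecision, dict]:
    """Compute the selected index for one variant and decide its verdict.

    Returns the decision plus a diagnostics dict (stratum counts and, when
    ``collect_all`` and a signal matrix was built, all four signal indexes).
    """
    extras: dict = {}
    if variant.window is None:
        return (
            decide(variant, None, config, reason="flank window truncated at contig end"),
            extras,
        )
    selected = select_index(config, variant.del_class)
    if selected is None:
        return decide(variant, None, config), extras
    index_name, _ = selected
    k = signal_flank_k if index_name == INDEX_MRPP else qscore_flank_k
    # parsing already validated the window at max(k); a smaller k always fits,
    # so the right-bound check can be skipped here
    window = variant.window if variant.window.k == k else flank_window(
        variant, k, contig_length=10**12
    )
    assignment = assign_reads(alignments, variant, window)
    sub = subsample_strand_specific(
        assignment,
        SubsampleSpec(n_per_stratum=config.strand_depth, seed=seed),
        contig=variant.contig,
        pos=variant.pos,
    )
    extras["stratum_counts"] = sub.stratum_counts
    if not sub.evaluable:
        return (
            decide(variant, None, config, reason="insufficient reads in a stratum"),
            extras,
        )
    value: float | None = None
    reason = ""
    if index_name == INDEX_MRPP:
        if signal_store is None:
            reason = "no signal store provided for the MRPP index"
        else:
            bins = n_bins or 10 * window.n_bases
            try:
                matrix = build_matrix(signal_store, sub.reads, window, bins)
                value = mrpp_a(matrix, mode=mrpp_mode, seed=seed)
                if collect_all:
                    gc = group_compare(matrix)
                    extras.update(
                        mrpp_a=gc.mrpp_a,
                        anosim_r=gc.anosim_r,
                        adonis_f=gc.adonis_f,
                        accum_diff=gc.accum_diff,
                    )
            except NotEvaluatedError as exc:
                reason = str(exc)
    elif index_name == INDEX_QSCORE:
        try:
            value = qscore_index(sub.reads, window).mean_q
        except NotEvaluatedError as exc:
            reason = str(exc)
    return decide(variant, value, config, reason=reason), extras


def run_filter(
    vcf_path,
    alignments,
    reference,
    config: SelectorConfig,
    signal_store: SignalStore | None = None,
    out_vcf=None,
    drop_artifacts: bool = False,
    min_muaf: float = 0.05,
    af_key: str = "AF",
    signal_flank_k: int = 5,
    qscore_flank_k: int = 5,
    n_bins: int | None = None,
    seed: int = 0,
    mrpp_mode: str = "analytic",
    collect_all: bool = False,
) -> PipelineResult:
    """Run the whole filter; optionally write the annotated/filtered VCF."""
    parsed = parse_deletions(
        vcf_path, reference, min_muaf=min_muaf, af_key=af_key,
        flank_k=max(signal_flank_k, qscore_flank_k),
    )
    decisions: list[FilterDecision] = []
    rows = []
    for variant in parsed:
        decision, extras = score_variant(
            variant,
            alignments,
            config,
            signal_store=signal_store,
            signal_flank_k=signal_flank_k,
            qscore_flank_k=qscore_flank_k,
            n_bins=n_bins,
            seed=seed,
            mrpp_mode=mrpp_mode,
            collect_all=collect_all,
        )
        decisions.append(decision)
        row = {
            "contig": variant.contig,
            "pos": variant.pos,
            "ref": variant.ref_allele,
            "alt": variant.alt_allele,
            "del_len": variant.del_len,
            "muaf": variant.muaf,
            "del_class": variant.del_class.value,
            "index": decision.index_name,
            "value": decision.index_value,
            "threshold": decision.threshold,
            "verdict": decision.verdict.value,
            "reason": decision.reason,
        }
        for key in ("mrpp_a", "anosim_r", "adonis_f", "accum_diff"):
            if key in extras:
                row[key] = extras[key]
        rows.append(row)
    result = PipelineResult(
        decisions=decisions,
        table=pd.DataFrame(rows),
        summary=summarize(decisions),
        parse_summary=parsed.summary,
    )
    if out_vcf is not None:
        write_filtered_vcf(
            decisions, vcf_path, out_vcf,
            drop_artifacts=drop_artifacts, config=config, seed=seed,
        )
    return result
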