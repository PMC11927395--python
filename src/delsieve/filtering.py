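"""Index selection, thresholding and annotated-VCF output.

The choice of index depends on how the run was produced:

* R9 flowcell, amplified (WTA/amplicon) library, strand depth >= 20x
  -> MRPP A, threshold 0.01;
* R9, direct library, strand depth >= 400x -> MRPP A, threshold 0.001;
* R9, direct, depth in [20x, 400x) -> mean flanking Q score, threshold 23
  (homopolymer deletions) / 20.6 (other deletions);
* R10, direct, SUP basecalls, depth >= 20x -> Q score, threshold 21.8 / 20.0.

R10 signal parsing is never needed (Q score only); R10 fast-model basecalls
are refused because their qualities do not separate artifacts from genuine
deletions; R10 HAC falls back to the SUP thresholds with a warning.  A variant
whose selected index is *strictly below* its threshold is called an artifact
(values equal to the threshold are kept); a variant whose index could not be
computed, or whose depth is below 20x per stratum, is NOT_EVALUATED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import pysam

from .variants import DelClass, DeletionVariant

MIN_STRAND_DEPTH = 20

INDEX_MRPP = "mrpp_a"
INDEX_QSCORE = "qscore"

ARTIFACT_FILTER_ID = "artifact_del"


class Flowcell(str, Enum):
    R9 = "R9"
    R10 = "R10"


class Protocol(str, Enum):
    AMPLIFIED = "AMPLIFIED"  # WTA or amplicon library
    DIRECT = "DIRECT"


class BasecallModel(str, Enum):
    SUP = "SUP"
    HAC = "HAC"
    FAST = "FAST"


class Verdict(str, Enum):
    KEEP = "KEEP"
    ARTIFACT = "ARTIFACT"
    NOT_EVALUATED = "NOT_EVALUATED"


class UnsupportedRunError(ValueError):
    """No index is applicable to this run configuration."""


#: Default selector table: (flowcell, protocol, depth band, del_class) ->
#: (index name, threshold).  Depth bands are closed on the left, open on the
#: right; ``None`` means unbounded.
DEFAULT_THRESHOLD_TABLE: tuple[
    tuple[Flowcell, Protocol, tuple[int, int | None], DelClass, str, float], ...
] = (
    (Flowcell.R9, Protocol.AMPLIFIED, (20, None), DelClass.HOMO_DEL, INDEX_MRPP, 0.01),
    (Flowcell.R9, Protocol.AMPLIFIED, (20, None), DelClass.OTHER_DEL, INDEX_MRPP, 0.01),
    (Flowcell.R9, Protocol.DIRECT, (400, None), DelClass.HOMO_DEL, INDEX_MRPP, 0.001),
    (Flowcell.R9, Protocol.DIRECT, (400, None), DelClass.OTHER_DEL, INDEX_MRPP, 0.001),
    (Flowcell.R9, Protocol.DIRECT, (20, 400), DelClass.HOMO_DEL, INDEX_QSCORE, 23.0),
    (Flowcell.R9, Protocol.DIRECT, (20, 400), DelClass.OTHER_DEL, INDEX_QSCORE, 20.6),
    (Flowcell.R10, Protocol.DIRECT, (20, None), DelClass.HOMO_DEL, INDEX_QSCORE, 21.8),
    (Flowcell.R10, Protocol.DIRECT, (20, None), DelClass.OTHER_DEL, INDEX_QSCORE, 20.0),
)


@dataclass
class SelectorConfig:
    """Run metadata that drives index/threshold selection."""

    flowcell: Flowcell
    protocol: Protocol
    basecall_model: BasecallModel = BasecallModel.SUP
    strand_depth: int = 100
    threshold_overrides: dict[tuple[str, DelClass], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flowcell = Flowcell(self.flowcell)
        self.protocol = Protocol(self.protocol)
        self.basecall_model = BasecallModel(self.basecall_model)


@dataclass
class FilterDecision:
    """Per-variant outcome of the filter."""

    variant: DeletionVariant
    index_name: str | None
    index_value: float | None
    threshold: float | None
    verdict: Verdict
    reason: str = ""


def select_index(config: SelectorConfig, del_class: DelClass) -> tuple[str, float] | None:
    """(index name, threshold) for a run configuration, or None when depth < 20x.

    Raises :class:`UnsupportedRunError` for combinations with no calibrated
    row (R10 fast basecalls, R10 amplified libraries).
    """
    if config.flowcell is Flowcell.R10 and config.basecall_model is BasecallModel.FAST:
        raise UnsupportedRunError(
            "R10 fast-model base qualities do not separate artificial from "
            "genuine deletions; re-basecall with SUP (or HAC) to filter"
        )
    if config.flowcell is Flowcell.R10 and config.protocol is Protocol.AMPLIFIED:
        raise UnsupportedRunError(
            "no calibrated index for R10 amplified libraries; use an R9 "
            "amplified or R10 direct configuration"
        )
    if config.strand_depth < MIN_STRAND_DEPTH:
        return None
    if config.flowcell is Flowcell.R10 and config.basecall_model is BasecallModel.HAC:
        warnings.warn(
            "Q-score thresholds were calibrated on SUP basecalls; applying "
            "them to HAC data",
            stacklevel=2,
        )
    for fc, proto, (lo, hi), dc, index, threshold in DEFAULT_THRESHOLD_TABLE:
        if fc is not config.flowcell or proto is not config.protocol or dc is not del_class:
            continue
        if config.strand_depth >= lo and (hi is None or config.strand_depth < hi):
            override = config.threshold_overrides.get((index, del_class))
            return index, threshold if override is None else override
    raise UnsupportedRunError(
        f"no selector row for {config.flowcell.value}/{config.protocol.value} "
        f"at strand depth {config.strand_depth}"
    )


def decide(
    variant: DeletionVariant,
    index_value: float | None,
    config: SelectorConfig,
    reason: str = "",
) -> FilterDecision:
    """Apply the strict-below-threshold rule to one variant."""
    selected = select_index(config, variant.del_class)
    if selected is None:
        return FilterDecision(
            variant, None, None, None, Verdict.NOT_EVALUATED,
            reason or f"strand depth < {MIN_STRAND_DEPTH}x",
        )
    index_name, threshold = selected
    if index_value is None:
        return FilterDecision(
            variant, index_name, None, threshold, Verdict.NOT_EVALUATED,
            reason or "index not computable",
        )
    verdict = Verdict.ARTIFACT if index_value < threshold else Verdict.KEEP
    return FilterDecision(variant, index_name, float(index_value), threshold, verdict)


def apply_filter(
    variants_with_indexes,
    config: SelectorConfig,
) -> list[FilterDecision]:
    """Decisions for (variant, index value or None) pairs, plus summary logging."""
    return [
        decide(variant, value, config) for variant, value in variants_with_indexes
    ]


def summarize(decisions) -> dict[str, int]:
    out = {v.value: 0 for v in Verdict}
    for d in decisions:
        out[d.verdict.value] += 1
    return out


_INFO_LINES = (
    ("DSV_INDEX", "1", "String", "Index used by the deletion filter"),
    ("DSV_VALUE", "1", "Float", "Value of the deletion-filter index"),
    ("DSV_THRESHOLD", "1", "Float", "Threshold applied by the deletion filter"),
    ("DSV_VERDICT", "1", "String", "Deletion-filter verdict (KEEP/ARTIFACT/NOT_EVALUATED)"),
)


def write_filtered_vcf(
    decisions,
    in_vcf,
    out_vcf,
    drop_artifacts: bool = False,
    config: SelectorConfig | None = None,
    seed: int | None = None,
) -> dict[str, int]:
    """Annotate (mark mode) or remove (drop mode) artifact deletions in a VCF.

    Non-deletion records pass through untouched.  Annotated records gain the
    ``artifact_del`` FILTER (artifacts only) and DSV_* INFO keys; the header
    records the tool version and run configuration.  Returns verdict counts.
    """
    from . import __version__

    by_key = {d.variant.key: d for d in decisions}
    counts = {v.value: 0 for v in Verdict}
    with pysam.VariantFile(str(in_vcf)) as vcf_in:
        header = vcf_in.header.copy()
        header.filters.add(ARTIFACT_FILTER_ID, None, None,
                           "Deletion judged artificial by the signal/Q-score filter")
        for name, number, vtype, desc in _INFO_LINES:
            header.info.add(name, number, vtype, desc)
        meta = f"delsieve_version={__version__}"
        if config is not None:
            meta += (
                f",flowcell={config.flowcell.value},protocol={config.protocol.value}"
                f",model={config.basecall_model.value},strand_depth={config.strand_depth}"
            )
        if seed is not None:
            meta += f",seed={seed}"
        header.add_line(f"##delsieve=<{meta}>")
        with pysam.VariantFile(str(out_vcf), "w", header=header) as vcf_out:
            for record in vcf_in:
                decision = None
                for alt in record.alts or ():
                    decision = by_key.get((record.contig, record.pos, record.ref, alt))
                    if decision is not None:
                        break
                record.translate(header)
                if decision is None:
                    vcf_out.write(record)
                    continue
                counts[decision.verdict.value] += 1
                if drop_artifacts and decision.verdict is Verdict.ARTIFACT:
                    continue
                new = record
                new.info["DSV_INDEX"] = decision.index_name or "none"
                if decision.index_value is not None:
                    new.info["DSV_VALUE"] = decision.index_value
                if decision.threshold is not None:
                    new.info["DSV_THRESHOLD"] = decision.threshold
                new.info["DSV_VERDICT"] = decision.verdict.value
                if decision.verdict is Verdict.ARTIFACT:
                    new.filter.add(ARTIFACT_FILTER_ID)
                vcf_out.write(new)
    return counts


def read_decisions_from_vcf(path) -> dict[tuple[str, int, str, str], str]:
    """Verdicts recorded in an annotated VCF, keyed like FilterDecision.variant.key."""
    out: dict[tuple[str, int, str, str], str] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for record in vcf:
            if "DSV_VERDICT" not in record.info:
                continue
            verdict = record.info["DSV_VERDICT"]
            if isinstance(verdict, tuple):
                verdict = verdict[0]
            for alt in record.alts or ():
                out[(record.contig, record.pos, record.ref, alt)] = str(verdict)
    return out
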