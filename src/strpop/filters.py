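"""Call-level quality filters (the dumpSTR parameter set, re-implemented).

Each filter is a pure predicate over :class:`~strpop.model.StrCall`; a call is
kept only when every enabled sub-filter passes, and every failed sub-filter is
reported (not just the first). Thresholds are inclusive on the keep side:
depth 50 and quality 0.90 are kept at defaults.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .model import StrCall, StrLocus

#: Read-class indices that bound allele length (enclosing, fully-repetitive).
SUPPORTING_READ_CLASSES = (0, 2)

REASON_MISSING = "missing"
REASON_MIN_DEPTH = "min_depth"
REASON_MAX_DEPTH = "max_depth"
REASON_MIN_QUALITY = "min_quality"
REASON_NO_SUPPORTING_READS = "no_supporting_reads"
REASON_SPANBOUND_ONLY = "spanbound_only"
REASON_ML_OUTSIDE_CI = "ml_outside_ci"


@dataclass(frozen=True)
class FilterParams:
    min_depth: int = 50
    max_depth: int = 1000
    min_quality: float = 0.90
    require_supported_reads: bool = True
    require_ml_in_ci: bool = True
    supporting_read_classes: tuple[int, ...] = SUPPORTING_READ_CLASSES

    def __post_init__(self) -> None:
        if not 0 <= self.min_depth <= self.max_depth:
            raise ValueError(
                f"need 0 <= min_depth <= max_depth, got {self.min_depth}/{self.max_depth}"
            )
        if not 0.0 <= self.min_quality <= 1.0:
            raise ValueError(f"min_quality must be in [0,1], got {self.min_quality}")


def filter_call(call: StrCall, params: FilterParams = FilterParams()) -> tuple[bool, list[str]]:
    """Apply all enabled sub-filters; return (keep, list of failed reasons)."""
    if call.missing:
        return False, [REASON_MISSING]
    reasons = []
    if call.depth < params.min_depth:
        reasons.append(REASON_MIN_DEPTH)
    if call.depth > params.max_depth:
        reasons.append(REASON_MAX_DEPTH)
    if call.quality < params.min_quality:
        reasons.append(REASON_MIN_QUALITY)
    if params.require_supported_reads:
        total = sum(call.read_counts)
        supporting = sum(call.read_counts[i] for i in params.supporting_read_classes)
        if total == 0:
            reasons.append(REASON_NO_SUPPORTING_READS)
        elif supporting == 0:
            reasons.append(REASON_SPANBOUND_ONLY)
    if params.require_ml_in_ci and call.ci_bp is not None:
        for allele, (lo, hi) in zip(call.allele_bp, call.ci_bp):
            if not lo <= allele <= hi:
                reasons.append(REASON_ML_OUTSIDE_CI)
                break
    return not reasons, reasons


@dataclass
class FilterSummary:
    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    dropped_by_reason: Counter = field(default_factory=Counter)

    def merge(self, other: "FilterSummary") -> None:
        self.n_input += other.n_input
        self.n_kept += other.n_kept
        self.n_dropped += other.n_dropped
        self.dropped_by_reason.update(other.dropped_by_reason)


def filter_cohort(
    calls_by_locus: Mapping[StrLocus, Iterable[StrCall]] | Iterable[tuple[StrLocus, Iterable[StrCall]]],
    params: FilterParams = FilterParams(),
) -> tuple[dict[StrLocus, list[StrCall]], FilterSummary]:
    """Filter every call per locus; kept + dropped always equals the input."""
    items = calls_by_locus.items() if isinstance(calls_by_locus, Mapping) else calls_by_locus
    kept: dict[StrLocus, list[StrCall]] = {}
    summary = FilterSummary()
    for locus, calls in items:
        kept_here = []
        for call in calls:
            summary.n_input += 1
            keep, reasons = filter_call(call, params)
            if keep:
                summary.n_kept += 1
                kept_here.append(call)
            else:
                summary.n_dropped += 1
                summary.dropped_by_reason.update(reasons)
        kept[locus] = kept_here
    return kept, summary


def filter_matrix(
    depth: np.ndarray,
    quality: np.ndarray,
    read_counts: np.ndarray,
    allele_bp: np.ndarray,
    ci_lo_bp: np.ndarray,
    ci_hi_bp: np.ndarray,
    missing: np.ndarray,
    params: FilterParams = FilterParams(),
) -> np.ndarray:
    """Vectorized keep-mask over array-shaped cohorts.

    Shapes: depth/quality/missing (L, S); read_counts (L, S, 4);
    allele_bp/ci_* (L, S, 2). Semantics identical to :func:`filter_call`
    (verified by a property test).
    """
    keep = ~missing
    keep &= depth >= params.min_depth
    keep &= depth <= params.max_depth
    keep &= quality >= params.min_quality
    if params.require_supported_reads:
        supporting = read_counts[..., list(params.supporting_read_classes)].sum(axis=-1)
        keep &= supporting > 0
    if params.require_ml_in_ci:
        in_ci = (ci_lo_bp <= allele_bp) & (allele_bp <= ci_hi_bp)
        keep &= in_ci.all(axis=-1)
    return keep
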