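"""Trio de novo STR mutation screen.

An *expansion* is a proband allele strictly longer than twice the longest
allele of either parent; a *contraction* is a proband allele strictly shorter
than half the shortest allele of either parent. The rule is deliberately
insensitive to single-repeat-unit stepwise mutations; it targets large jumps.
All three trio members must have filter-passing calls at a locus for it to be
screened.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as scipy_stats

from .model import DeNovoEvent, Sample, StrCall, StrLocus


def detect_denovo(
    proband: StrCall,
    mother: StrCall,
    father: StrCall,
    locus: StrLocus,
    family_id: str,
    expansion_factor: float = 2.0,
    contraction_factor: float = 0.5,
) -> list[DeNovoEvent]:
    """Detect de novo events at one locus for one trio (0-2 events).

    An expansion and a contraction can co-occur (one on each proband allele).
    """
    if any(c.missing for c in (proband, mother, father)):
        return []
    parent_max = max(mother.longest_bp, father.longest_bp)
    parent_min = min(mother.shortest_bp, father.shortest_bp)
    events = []
    if proband.longest_bp > expansion_factor * parent_max:
        events.append(
            DeNovoEvent(
                family_id=family_id,
                locus=locus,
                type="expansion",
                proband_allele_bp=proband.longest_bp,
                parental_extreme_bp=parent_max,
                fold=proband.longest_bp / parent_max,
            )
        )
    if proband.shortest_bp < contraction_factor * parent_min:
        events.append(
            DeNovoEvent(
                family_id=family_id,
                locus=locus,
                type="contraction",
                proband_allele_bp=proband.shortest_bp,
                parental_extreme_bp=parent_min,
                fold=parent_min / proband.shortest_bp,
            )
        )
    return events


@dataclass
class TrioScanResult:
    events: list[DeNovoEvent]
    expansions_per_proband: dict[str, int]
    contractions_per_proband: dict[str, int]
    n_loci_screened: dict[str, int]
    n_loci_incomplete: dict[str, int] = field(default_factory=dict)

    @property
    def mean_expansions(self) -> float:
        counts = list(self.expansions_per_proband.values())
        return float(np.mean(counts)) if counts else math.nan

    @property
    def expansion_range(self) -> tuple[int, int]:
        counts = list(self.expansions_per_proband.values())
        return (min(counts), max(counts)) if counts else (0, 0)


def scan_trios(
    calls_by_locus: Mapping[StrLocus, Iterable[StrCall]],
    trios: Sequence[tuple[Sample, Sample, Sample]],
    expansion_factor: float = 2.0,
    contraction_factor: float = 0.5,
) -> TrioScanResult:
    """Scan every trio across every locus; loci with an incomplete trio
    (any member missing or filtered out) are skipped and counted."""
    events: list[DeNovoEvent] = []
    exp_counts = {p.sample_id: 0 for p, _, _ in trios}
    con_counts = {p.sample_id: 0 for p, _, _ in trios}
    screened = {p.sample_id: 0 for p, _, _ in trios}
    incomplete = {p.sample_id: 0 for p, _, _ in trios}
    for locus in sorted(calls_by_locus, key=lambda l: (l.chrom, l.pos, l.repeat_unit)):
        calls = {c.sample_id: c for c in calls_by_locus[locus] if not c.missing}
        for proband, mother, father in trios:
            trio_calls = [calls.get(s.sample_id) for s in (proband, mother, father)]
            if any(c is None for c in trio_calls):
                incomplete[proband.sample_id] += 1
                continue
            screened[proband.sample_id] += 1
            found = detect_denovo(
                trio_calls[0], trio_calls[1], trio_calls[2],
                locus, proband.family_id, expansion_factor, contraction_factor,
            )
            for ev in found:
                if ev.type == "expansion":
                    exp_counts[proband.sample_id] += 1
                else:
                    con_counts[proband.sample_id] += 1
            events.extend(found)
    return TrioScanResult(events, exp_counts, con_counts, screened, incomplete)


def parental_age_summary(
    counts_per_proband: Mapping[str, int],
    samples: Sequence[Sample],
) -> dict[str, dict]:
    """Pearson correlation of per-proband event counts with parental ages.

    Reports r, the p-value and n for each parent; zero variance in either
    variable or n < 3 yields an undefined entry with the reason.
    """
    by_id = {s.sample_id: s for s in samples}
    out = {}
    for which, attr in (("maternal", "maternal_age_years"), ("paternal", "paternal_age_years")):
        xs, ys = [], []
        for sid, count in counts_per_proband.items():
            s = by_id.get(sid)
            age = getattr(s, attr, None) if s else None
            if age is not None:
                xs.append(age)
                ys.append(count)
        entry: dict = {"n": len(xs)}
        if len(xs) < 3:
            entry.update(r=math.nan, p=math.nan, defined=False, reason="fewer than 3 probands with ages")
        elif np.std(xs) == 0 or np.std(ys) == 0:
            entry.update(r=math.nan, p=math.nan, defined=False, reason="zero variance")
        else:
            r, p = scipy_stats.pearsonr(xs, ys)
            entry.update(r=float(r), p=float(p), defined=True, reason=None)
        out[which] = entry
    return out
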