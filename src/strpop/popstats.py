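"""Per-locus allele-length summary statistics per ancestry group.

Both alleles of every individual contribute (pooled-allele convention);
the standard deviation is the population SD (ddof 0) and the coefficient of
variation cov = sd/mean is the conservation metric used downstream. A
single-pass accumulator backs the per-locus API; a vectorized array path
produces whole-cohort baselines. The two agree exactly on tallies and to
floating-point round-off on moments.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ANCESTRY_GROUPS, GroupLocusStats, Sample, StrCall, StrLocus, TOTAL_GROUP

BASELINE_COLUMNS = ["chrom", "pos", "repeat_unit", "group", "n", "mean", "sd", "cov", "se"]


class CohortConfigError(ValueError):
    pass


@dataclass
class GroupStatsAccumulator:
    """Streaming tally/moment accumulator for one (locus, group) cell."""

    tally: Counter = field(default_factory=Counter)
    n: int = 0
    total: int = 0
    total_sq: int = 0

    def add(self, lengths: Iterable[int]) -> None:
        for x in lengths:
            self.tally[int(x)] += 1
            self.n += 1
            self.total += int(x)
            self.total_sq += int(x) * int(x)

    def finalize(self, locus: StrLocus, group: str) -> GroupLocusStats:
        if self.n == 0:
            return GroupLocusStats(locus, group, 0, math.nan, math.nan, math.nan, math.nan, {})
        mean = self.total / self.n
        var = max(self.total_sq / self.n - mean * mean, 0.0)
        sd = math.sqrt(var)
        cov = sd / mean if mean > 0 else math.nan
        se = sd / math.sqrt(self.n)
        return GroupLocusStats(locus, group, self.n, mean, sd, cov, se, dict(self.tally))


def compute_group_stats(
    calls: Iterable[StrCall],
    assignment: Mapping[str, str],
    locus: StrLocus,
    mode: str = "pooled",
) -> list[GroupLocusStats]:
    """Summaries for every ancestry group plus TOTAL at one locus.

    ``assignment`` maps sample id to primary ancestry group. ``mode`` is
    ``"pooled"`` (both alleles, the default) or ``"longest"`` (one allele per
    individual).
    """
    accs: dict[str, GroupStatsAccumulator] = {g: GroupStatsAccumulator() for g in ANCESTRY_GROUPS}
    total = GroupStatsAccumulator()
    for call in calls:
        if call.missing:
            continue
        if call.sample_id not in assignment:
            raise CohortConfigError(
                f"sample {call.sample_id} has calls but no ancestry assignment"
            )
        group = assignment[call.sample_id]
        lengths = call.allele_bp if mode == "pooled" else (call.longest_bp,)
        if group in accs:
            accs[group].add(lengths)
        total.add(lengths)
    out = [accs[g].finalize(locus, g) for g in ANCESTRY_GROUPS]
    out.append(total.finalize(locus, TOTAL_GROUP))
    return out


def population_cohort_ids(samples: Sequence[Sample]) -> list[str]:
    """Membership rule for the baseline cohort.

    All parents, plus probands with neither parent sequenced. Siblings are
    excluded from all analyses.
    """
    families_with_parents = {s.family_id for s in samples if s.role in ("mother", "father")}
    out = []
    for s in samples:
        if s.role in ("mother", "father"):
            out.append(s.sample_id)
        elif s.role == "proband" and s.family_id not in families_with_parents:
            out.append(s.sample_id)
    return out


def stats_to_frame(stats: Iterable[GroupLocusStats]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.locus.chrom,
            "pos": s.locus.pos,
            "repeat_unit": s.locus.repeat_unit,
            "group": s.group,
            "n": s.n_alleles,
            "mean": s.mean_bp,
            "sd": s.sd_bp,
            "cov": s.cov,
            "se": s.se_bp,
        }
        for s in stats
    ]
    return pd.DataFrame(rows, columns=BASELINE_COLUMNS)


def build_population_baseline(
    calls_by_locus: Mapping[StrLocus, Iterable[StrCall]] | Iterable[tuple[StrLocus, Iterable[StrCall]]],
    samples: Sequence[Sample],
    assignment: Mapping[str, str],
    mode: str = "pooled",
) -> pd.DataFrame:
    """Per-locus x per-group baseline table from filtered calls.

    Only population-cohort members (see :func:`population_cohort_ids`)
    contribute. Returns a DataFrame with BASELINE_COLUMNS, one row per
    (locus, group) including TOTAL.
    """
    member_ids = set(population_cohort_ids(samples))
    if not member_ids:
        raise CohortConfigError("population cohort is empty")
    items = calls_by_locus.items() if isinstance(calls_by_locus, Mapping) else calls_by_locus
    frames = []
    for locus, calls in items:
        cohort_calls = [c for c in calls if c.sample_id in member_ids]
        frames.append(stats_to_frame(compute_group_stats(cohort_calls, assignment, locus, mode)))
    if not frames:
        raise CohortConfigError("no loci in cohort")
    return pd.concat(frames, ignore_index=True)


def baseline_from_arrays(
    loci: Sequence[StrLocus],
    allele_bp: np.ndarray,
    keep: np.ndarray,
    sample_ids: Sequence[str],
    assignment: Mapping[str, str],
    member_ids: Optional[set[str]] = None,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Vectorized baseline over an array-shaped cohort.

    ``allele_bp``: (L, S, 2) integer lengths; ``keep``: (L, S) boolean mask of
    filter-passing, non-missing calls. Agrees with
    :func:`build_population_baseline` (tested).
    """
    sample_ids = list(sample_ids)
    if member_ids is None:
        member_ids = set(sample_ids)
    groups = np.array([assignment.get(s, "") for s in sample_ids])
    member = np.array([s in member_ids for s in sample_ids])
    a = allele_bp.astype(float)
    if mode == "longest":
        a = a.max(axis=2, keepdims=True)
    rows = []
    n_loci = len(loci)
    group_masks = [(g, (groups == g) & member) for g in ANCESTRY_GROUPS]
    group_masks.append((TOTAL_GROUP, member))
    for g, smask in group_masks:
        if not smask.any():
            n = np.zeros(n_loci, dtype=int)
            mean = sd = cov = se = np.full(n_loci, np.nan)
        else:
            sub = a[:, smask, :]
            kmask = np.repeat(keep[:, smask, None], sub.shape[2], axis=2)
            n = kmask.sum(axis=(1, 2))
            tot = np.where(kmask, sub, 0.0).sum(axis=(1, 2))
            tot_sq = np.where(kmask, sub * sub, 0.0).sum(axis=(1, 2))
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = np.where(n > 0, tot / np.maximum(n, 1), np.nan)
                msq = np.where(n > 0, tot_sq / np.maximum(n, 1), np.nan)
                sd = np.sqrt(np.maximum(msq - mean * mean, 0.0))
                cov = np.where(mean > 0, sd / mean, np.nan)
                se = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": [l.chrom for l in loci],
                    "pos": [l.pos for l in loci],
                    "repeat_unit": [l.repeat_unit for l in loci],
                    "group": g,
                    "n": n,
                    "mean": mean,
                    "sd": sd,
                    "cov": cov,
                    "se": se,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def save_baseline(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_baseline(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "repeat_unit": str})
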