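"""Ancestry-divergence screen: loci whose mean allele length in a
non-European group departs from the European mean.

A locus is divergent when |z| > 5 and the relative difference from the
European mean exceeds 20% (both strict). z uses the European SD as
denominator: z = (mean_group - mean_EUR) / sd_EUR; a two-sample z using
combined standard errors is available via ``z_mode="two_sample"``.
"""
from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import DivergentPosition, GroupLocusStats, StrLocus

log = logging.getLogger(__name__)

Z_THRESHOLD = 5.0
PCT_THRESHOLD = 0.20
MIN_ALLELES = 10


def divergence_test(
    group_stats: GroupLocusStats,
    eur_stats: GroupLocusStats,
    z_threshold: float = Z_THRESHOLD,
    pct_threshold: float = PCT_THRESHOLD,
    z_mode: str = "eur_sd",
) -> Optional[DivergentPosition]:
    """Compare one group's mean to the European mean at one locus.

    Returns None when the European mean is zero (undefined percent
    difference). Zero European SD with unequal means yields z = +/-inf and the
    divergence decision then rests on the percent criterion.
    """
    if eur_stats.mean_bp == 0 or math.isnan(eur_stats.mean_bp):
        log.warning("locus %s: European mean undefined/zero, skipped", group_stats.locus)
        return None
    diff = group_stats.mean_bp - eur_stats.mean_bp
    if z_mode == "two_sample":
        denom = math.hypot(group_stats.se_bp, eur_stats.se_bp)
    else:
        denom = eur_stats.sd_bp
    if denom == 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        if diff != 0:
            log.warning("locus %s: zero European SD, z set to %s", group_stats.locus, z)
    else:
        z = diff / denom
    pct = abs(diff) / eur_stats.mean_bp
    divergent = abs(z) > z_threshold and pct > pct_threshold
    return DivergentPosition(
        locus=group_stats.locus,
        group=group_stats.group,
        z=z,
        pct_diff=pct,
        mean_group_bp=group_stats.mean_bp,
        mean_eur_bp=eur_stats.mean_bp,
        divergent=divergent,
    )


def screen_all_loci(
    baseline: pd.DataFrame,
    group: str,
    z_threshold: float = Z_THRESHOLD,
    pct_threshold: float = PCT_THRESHOLD,
    min_n: int = MIN_ALLELES,
    z_mode: str = "eur_sd",
) -> tuple[list[DivergentPosition], pd.DataFrame]:
    """Screen every baseline locus for divergence of ``group`` vs EUR.

    Returns (divergent records, scatter table of per-locus means for both
    groups). Loci where either group has fewer than ``min_n`` alleles or the
    European SD/mean is degenerate are excluded from the scatter table's
    divergence calls but still listed with NaN z.
    """
    if group == "EUR":
        raise ValueError("self-comparison EUR vs EUR is meaningless")
    key = ["chrom", "pos", "repeat_unit"]
    g = baseline[baseline["group"] == group].set_index(key)
    e = baseline[baseline["group"] == "EUR"].set_index(key)
    joined = g.join(e, lsuffix="_g", rsuffix="_e", how="inner").reset_index()
    ok = (joined["n_g"] >= min_n) & (joined["n_e"] >= min_n) & (joined["mean_e"] > 0)
    diff = joined["mean_g"] - joined["mean_e"]
    if z_mode == "two_sample":
        denom = np.hypot(joined["se_g"], joined["se_e"])
    else:
        denom = joined["sd_e"]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, diff / denom, np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
        pct = np.abs(diff) / joined["mean_e"]
    divergent = ok & (np.abs(z) > z_threshold) & (pct > pct_threshold)
    scatter = pd.DataFrame(
        {
            "chrom": joined["chrom"],
            "pos": joined["pos"],
            "repeat_unit": joined["repeat_unit"],
            "mean_eur": joined["mean_e"],
            "mean_group": joined["mean_g"],
            "z": np.where(ok, z, np.nan),
            "pct_diff": np.where(ok, pct, np.nan),
            "divergent": divergent,
        }
    )
    records = []
    for row in scatter[scatter["divergent"]].itertuples(index=False):
        records.append(
            DivergentPosition(
                locus=StrLocus(row.chrom, int(row.pos), row.repeat_unit, 1),
                group=group,
                z=float(row.z),
                pct_diff=float(row.pct_diff),
                mean_group_bp=float(row.mean_group),
                mean_eur_bp=float(row.mean_eur),
                divergent=True,
            )
        )
    return records, scatter


def top_divergent(records: Sequence[DivergentPosition], k: int = 20) -> list[DivergentPosition]:
    """Top-k by |z| descending; ties by pct_diff descending then locus key."""
    return sorted(
        records,
        key=lambda r: (-abs(r.z), -r.pct_diff, r.locus.chrom, r.locus.pos, r.locus.repeat_unit),
    )[:k]


def shared_loci(
    top_lists: dict[str, Sequence[DivergentPosition]], min_groups: int = 2
) -> dict[tuple[str, int, str], set[str]]:
    """Loci appearing in the top lists of at least ``min_groups`` groups."""
    if len(top_lists) < 2:
        raise ValueError("need top lists from at least two groups")
    by_locus: dict[tuple[str, int, str], set[str]] = {}
    for group, records in top_lists.items():
        for r in records:
            by_locus.setdefault(r.locus.key, set()).add(group)
    return {k: v for k, v in by_locus.items() if len(v) >= min_groups}
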