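"""Conserved-locus outlier screen.

A locus is *conserved* when its total-population coefficient of variation
(sd/mean, the dimensionless spread of allele lengths) is at most 0.075. At
conserved loci a proband is flagged in two stages: first when the longest
allele lies more than 3 population SDs above the mean, then additionally when
it is at least 2.5x the mean. Both stage outputs are reported.

The 250% criterion is a ratio (allele >= 2.5 x mean) by default;
``ratio_mode="excess"`` switches to the relative-difference reading
((allele - mean)/mean >= 2.5).
"""
from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import pandas as pd

from .model import ConservedHit, StrCall, StrLocus

log = logging.getLogger(__name__)

COV_THRESHOLD = 0.075
SD_MULT = 3.0
RATIO_MIN = 2.5
MIN_ALLELES = 10


def classify_conserved(
    mean_bp: float,
    cov: float,
    n_alleles: int,
    cov_threshold: float = COV_THRESHOLD,
    min_n: int = MIN_ALLELES,
) -> bool:
    """Conserved iff cov <= threshold (inclusive), with a defined mean."""
    if not mean_bp > 0 or math.isnan(mean_bp) or math.isnan(cov):
        log.warning("degenerate mean %s: locus not classifiable as conserved", mean_bp)
        return False
    if n_alleles < min_n:
        return False
    return cov <= cov_threshold


def evaluate_outlier(
    allele_bp: float,
    mean_bp: float,
    sd_bp: float,
    sd_mult: float = SD_MULT,
    ratio_min: float = RATIO_MIN,
    ratio_mode: str = "ratio",
) -> tuple[float, float, bool, bool]:
    """Return (z, ratio, stage-1 outlier flag, final flag) for one allele.

    Zero SD leaves z undefined (inf for any exceedance); the decision then
    rests on the ratio criterion alone.
    """
    ratio = allele_bp / mean_bp
    diff = allele_bp - mean_bp
    if sd_bp == 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        outlier_3sd = diff > 0
        if diff > 0:
            log.warning("zero SD at conserved locus: outlier decided by ratio alone")
    else:
        z = diff / sd_bp
        outlier_3sd = z > sd_mult
    ratio_stat = ratio if ratio_mode == "ratio" else diff / mean_bp
    flagged = outlier_3sd and ratio_stat >= ratio_min
    return z, ratio, outlier_3sd, flagged


def screen_conserved_outliers(
    proband_calls: Mapping[StrLocus, Iterable[StrCall]],
    baseline: pd.DataFrame,
    cov_threshold: float = COV_THRESHOLD,
    sd_mult: float = SD_MULT,
    ratio_min: float = RATIO_MIN,
    ratio_mode: str = "ratio",
    min_n: int = MIN_ALLELES,
) -> list[ConservedHit]:
    """Flag proband expansions at conserved loci.

    Returns one hit per (conserved locus, proband) whose longest allele
    passes the 3-SD stage; ``flagged`` marks those that also pass the 250%
    stage.
    """
    totals = (
        baseline[baseline["group"] == "TOTAL"]
        .set_index(["chrom", "pos", "repeat_unit"])
        .sort_index()
    )
    hits: list[ConservedHit] = []
    for locus, calls in proband_calls.items():
        if locus.key not in totals.index:
            continue
        row = totals.loc[locus.key]
        mean, sd, cov, n = float(row["mean"]), float(row["sd"]), float(row["cov"]), int(row["n"])
        if not classify_conserved(mean, cov, n, cov_threshold, min_n):
            continue
        for call in calls:
            if call.missing:
                continue
            allele = call.longest_bp
            z, ratio, outlier_3sd, flagged = evaluate_outlier(
                allele, mean, sd, sd_mult, ratio_min, ratio_mode
            )
            if not outlier_3sd:
                continue
            hits.append(
                ConservedHit(
                    locus=locus,
                    sample_id=call.sample_id,
                    allele_bp=allele,
                    total_mean_bp=mean,
                    total_sd_bp=sd,
                    cov=cov,
                    z_individual=z,
                    ratio=ratio,
                    outlier_3sd=outlier_3sd,
                    flagged=flagged,
                )
            )
    hits.sort(key=lambda h: (h.locus.chrom, h.locus.pos, h.sample_id))
    return hits
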