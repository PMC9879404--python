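"""Screen probands at catalogued pathogenic repeat-expansion loci.

Two independent flags per proband x catalog locus:

* ``divergent`` — longest allele >= ratio_threshold x the total-population
  mean at that locus (default 1.5x, the criterion behind the per-gene
  divergent counts);
* ``exceeds_pathogenic`` — longest allele strictly longer than the published
  pathogenic length.

Neither implies the other: a modest allele can exceed a short pathogenic
cutoff, and a large allele at a long-mean locus can stay below it.
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import PathogenicHit, PathogenicLocusRecord, StrCall, StrLocus

log = logging.getLogger(__name__)

RATIO_THRESHOLD = 1.5


def _total_stats(baseline: pd.DataFrame) -> pd.DataFrame:
    return (
        baseline[baseline["group"] == "TOTAL"]
        .set_index(["chrom", "pos", "repeat_unit"])
        .sort_index()
    )


def screen_pathogenic(
    proband_calls: Mapping[StrLocus, Iterable[StrCall]],
    catalog: Sequence[PathogenicLocusRecord],
    baseline: pd.DataFrame,
    ratio_threshold: float = RATIO_THRESHOLD,
    assignment: Optional[Mapping[str, str]] = None,
    allele_mode: str = "longest",
) -> list[PathogenicHit]:
    """Evaluate every proband call at every catalog locus.

    Returns one hit record per (proband, catalog locus) with both flags set;
    catalog loci absent from the baseline are skipped with a warning.
    """
    totals = _total_stats(baseline)
    calls_by_key = {locus.key: (locus, list(calls)) for locus, calls in proband_calls.items()}
    hits: list[PathogenicHit] = []
    for rec in catalog:
        key = rec.locus.key
        if key not in totals.index:
            log.warning("catalog locus %s (%s) absent from baseline, skipped", key, rec.gene)
            continue
        mean = float(totals.loc[key, "mean"])
        if not mean > 0 or math.isnan(mean):
            log.warning("catalog locus %s (%s): degenerate baseline mean, skipped", key, rec.gene)
            continue
        locus, calls = calls_by_key.get(key, (rec.locus, []))
        for call in calls:
            if call.missing:
                continue
            alleles = [call.longest_bp] if allele_mode == "longest" else list(call.allele_bp)
            for allele in alleles:
                ratio = allele / mean
                hits.append(
                    PathogenicHit(
                        sample_id=call.sample_id,
                        gene=rec.gene,
                        locus=locus,
                        allele_bp=allele,
                        total_mean_bp=mean,
                        ratio=ratio,
                        divergent=ratio >= ratio_threshold,
                        exceeds_pathogenic=allele > rec.pathogenic_length_bp,
                        ancestry=assignment.get(call.sample_id) if assignment else None,
                    )
                )
    return hits


def _breakdown_bucket(ancestry: Optional[str]) -> str:
    if ancestry in ("AdmixedAMR", "NonadmixedAMR"):
        return "AMR"
    if ancestry == "EUR":
        return "EUR"
    return "Other"


def summarize_by_gene(hits: Sequence[PathogenicHit]) -> pd.DataFrame:
    """Per-gene counts of divergent probands and pathogenic exceedances,
    with the divergent ancestry breakdown pooled as AMR : EUR : Other."""
    genes = sorted({h.gene for h in hits})
    by_gene: dict[str, dict] = {
        g: {"divergent": 0, "exceeds": 0, "breakdown": defaultdict(int)} for g in genes
    }
    for h in hits:
        cell = by_gene[h.gene]
        if h.divergent:
            cell["divergent"] += 1
            cell["breakdown"][_breakdown_bucket(h.ancestry)] += 1
        if h.exceeds_pathogenic:
            cell["exceeds"] += 1
    rows = []
    for g in genes:
        b = by_gene[g]["breakdown"]
        rows.append(
            {
                "gene": g,
                "n_divergent": by_gene[g]["divergent"],
                "ethnic_breakdown": f"{b['AMR']}:{b['EUR']}:{b['Other']}",
                "n_exceeds_pathogenic": by_gene[g]["exceeds"],
            }
        )
    return pd.DataFrame(rows, columns=["gene", "n_divergent", "ethnic_breakdown", "n_exceeds_pathogenic"])


def ancestral_mean_at_pathogenic_loci(
    baseline: pd.DataFrame, catalog: Sequence[PathogenicLocusRecord]
) -> pd.DataFrame:
    """Mean allele length per (gene, ancestry) at the catalog loci.

    Cells where a group has no alleles are left as NaN.
    """
    idx = baseline.set_index(["chrom", "pos", "repeat_unit"]).sort_index()
    rows = []
    for rec in catalog:
        if rec.locus.key not in idx.index:
            continue
        sub = idx.loc[[rec.locus.key]]
        for r in sub.itertuples():
            if r.group == "TOTAL":
                continue
            rows.append(
                {
                    "gene": rec.gene,
                    "ancestry": r.group,
                    "mean_bp": r.mean if r.n > 0 else math.nan,
                    "n_alleles": r.n,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "ancestry", "mean_bp", "n_alleles"])
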