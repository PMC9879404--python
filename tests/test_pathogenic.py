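"""Pathogenic-locus expansion screen."""
import math

import pandas as pd
import pytest

from strpop.model import PathogenicHit, PathogenicLocusRecord, StrLocus
from strpop.pathogenic import (
    ancestral_mean_at_pathogenic_loci,
    screen_pathogenic,
    summarize_by_gene,
)
from strpop.popstats import BASELINE_COLUMNS

from conftest import make_call

AR = PathogenicLocusRecord(
    gene="AR", locus=StrLocus("X", 66765160, "GCA", 66), pathogenic_length_bp=114
)
TCF4 = PathogenicLocusRecord(
    gene="TCF4", locus=StrLocus("18", 53253385, "CTG", 75), pathogenic_length_bp=150
)


def _baseline(rows):
    return pd.DataFrame(rows, columns=BASELINE_COLUMNS)


def _total_row(locus, mean, sd=1.0, n=400, group="TOTAL"):
    return (locus.chrom, locus.pos, locus.repeat_unit, group, n, mean, sd,
            sd / mean, sd / math.sqrt(n))


@pytest.fixture
def two_gene_baseline():
    return _baseline([_total_row(AR.locus, 66.0), _total_row(TCF4.locus, 75.0)])


def test_divergent_without_pathogenic_exceedance(two_gene_baseline):
    """An AR allele of 110 bp is divergent (>= 1.5x the 66 bp mean) but does
    not exceed the 114 bp pathogenic length."""
    calls = {AR.locus: [make_call(sample_id="P1", allele_bp=(66, 110))]}
    [hit] = screen_pathogenic(calls, [AR], two_gene_baseline)
    assert hit.divergent and not hit.exceeds_pathogenic
    assert hit.ratio == pytest.approx(110 / 66)


def test_pathogenic_exceedance_at_tcf4(two_gene_baseline):
    """A TCF4 allele of 151 bp strictly exceeds the 150 bp pathogenic length."""
    calls = {TCF4.locus: [make_call(sample_id="P1", allele_bp=(75, 151))]}
    [hit] = screen_pathogenic(calls, [TCF4], two_gene_baseline)
    assert hit.exceeds_pathogenic and hit.divergent


def test_exceedance_is_strict_at_the_pathogenic_length(two_gene_baseline):
    calls = {TCF4.locus: [make_call(sample_id="P1", allele_bp=(75, 150))]}
    [hit] = screen_pathogenic(calls, [TCF4], two_gene_baseline)
    assert not hit.exceeds_pathogenic


def test_ratio_threshold_is_inclusive(two_gene_baseline):
    """An allele exactly at 1.5x the mean counts as divergent."""
    calls = {AR.locus: [make_call(sample_id="P1", allele_bp=(66, 99))]}
    [hit] = screen_pathogenic(calls, [AR], two_gene_baseline)
    assert hit.ratio == pytest.approx(1.5)
    assert hit.divergent


def test_exceedance_without_divergence_is_possible():
    """A 151 bp allele at a locus whose population mean is 140 bp exceeds the
    150 bp cutoff without reaching 1.5x the mean."""
    baseline = _baseline([_total_row(TCF4.locus, 140.0)])
    calls = {TCF4.locus: [make_call(sample_id="P1", allele_bp=(140, 151))]}
    [hit] = screen_pathogenic(calls, [TCF4], baseline)
    assert hit.exceeds_pathogenic and not hit.divergent


def test_raising_ratio_threshold_never_increases_divergent_count(two_gene_baseline):
    calls = {
        AR.locus: [
            make_call(sample_id=f"P{i}", allele_bp=(66, a))
            for i, a in enumerate((70, 100, 110, 140, 170))
        ]
    }
    counts = []
    for thr in (1.0, 1.5, 2.0, 2.5):
        hits = screen_pathogenic(calls, [AR], two_gene_baseline, ratio_threshold=thr)
        counts.append(sum(h.divergent for h in hits))
    assert counts == sorted(counts, reverse=True)


def test_catalog_locus_missing_from_baseline_is_skipped(two_gene_baseline, caplog):
    rogue = PathogenicLocusRecord(
        gene="HTT", locus=StrLocus("4", 3076604, "CAG", 57), pathogenic_length_bp=120
    )
    with caplog.at_level("WARNING"):
        hits = screen_pathogenic({}, [rogue], two_gene_baseline)
    assert hits == []
    assert "absent from baseline" in caplog.text


def test_missing_calls_are_ignored(two_gene_baseline):
    calls = {AR.locus: [make_call(sample_id="P1", missing=True)]}
    assert screen_pathogenic(calls, [AR], two_gene_baseline) == []


# ---------------------------------------------------------------------------
# per-gene summary


def _hit(gene, sample, divergent, exceeds, ancestry):
    return PathogenicHit(sample, gene, AR.locus, 100, 66.0, 1.5, divergent, exceeds, ancestry)


def test_summary_counts_zero_hits():
    df = summarize_by_gene([])
    assert df.empty


def test_summary_ancestry_breakdown_pools_amr_groups():
    hits = [
        _hit("AR", "P1", True, False, "AdmixedAMR"),
        _hit("AR", "P2", True, False, "EUR"),
        _hit("AR", "P3", True, True, "EAS"),
        _hit("AR", "P4", False, False, "EUR"),
        _hit("AR", "P5", True, False, "NonadmixedAMR"),
    ]
    df = summarize_by_gene(hits)
    row = df.iloc[0]
    assert row["n_divergent"] == 4
    assert row["ethnic_breakdown"] == "2:1:1"
    assert row["n_exceeds_pathogenic"] == 1


def test_summary_matches_injection_truth(small_cohort, catalog):
    from strpop.filters import filter_matrix
    from strpop.popstats import baseline_from_arrays, population_cohort_ids

    c = small_cohort
    keep = filter_matrix(
        c.depth, c.quality, c.read_counts, c.allele_bp, c.ci_lo_bp, c.ci_hi_bp, c.missing
    )
    baseline = baseline_from_arrays(
        c.loci, c.allele_bp, keep, c.sample_ids, c.truth.true_group,
        set(population_cohort_ids(c.samples)),
    )
    probands = {s.sample_id for s in c.samples if s.role == "proband"}
    proband_calls = {
        locus: [x for x in calls if x.sample_id in probands]
        for locus, calls in c.iter_calls()
    }
    hits = screen_pathogenic(proband_calls, catalog, baseline, assignment=c.truth.true_group)
    carriers = {(t["sample"], t["gene"]) for t in c.truth.pathogenic_carriers}
    flagged = {(h.sample_id, h.gene) for h in hits if h.divergent}
    assert flagged == carriers
    df = summarize_by_gene(hits)
    assert int(df.set_index("gene").loc["TCF4", "n_exceeds_pathogenic"]) == len(carriers)


# ---------------------------------------------------------------------------
# ancestral means at catalog loci


def test_ancestral_mean_table_shape_and_empty_cells():
    rows = [
        _total_row(AR.locus, 66.0),
        _total_row(AR.locus, 64.0, group="EUR"),
        _total_row(AR.locus, 70.0, group="AFR"),
        (AR.locus.chrom, AR.locus.pos, AR.locus.repeat_unit, "PAC", 0,
         math.nan, math.nan, math.nan, math.nan),
    ]
    df = ancestral_mean_at_pathogenic_loci(_baseline(rows), [AR])
    assert len(df) == 3  # one per non-TOTAL group present
    pac = df[df["ancestry"] == "PAC"]
    assert math.isnan(pac["mean_bp"].iloc[0])


def test_identical_group_distributions_have_close_means(small_cohort, catalog):
    from strpop.filters import filter_matrix
    from strpop.popstats import baseline_from_arrays, population_cohort_ids

    c = small_cohort
    keep = filter_matrix(
        c.depth, c.quality, c.read_counts, c.allele_bp, c.ci_lo_bp, c.ci_hi_bp, c.missing
    )
    baseline = baseline_from_arrays(
        c.loci, c.allele_bp, keep, c.sample_ids, c.truth.true_group,
        set(population_cohort_ids(c.samples)),
    )
    df = ancestral_mean_at_pathogenic_loci(baseline, catalog)
    # AR locus has no injections: group means all within 2 SE of each other
    sub = df[(df["gene"] == "AR") & (df["n_alleles"] > 0)]
    key = baseline.set_index(["chrom", "pos", "repeat_unit", "group"]).sort_index()
    ses = key.loc[("X", 66765160, "GCA"), "se"]
    spread = sub["mean_bp"].max() - sub["mean_bp"].min()
    assert spread <= 4 * ses.max()
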