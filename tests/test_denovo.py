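"""Trio de novo expansion/contraction detection."""
import math

import numpy as np
import pytest

from strpop.denovo import detect_denovo, parental_age_summary, scan_trios
from strpop.model import Sample, StrLocus
from strpop.simulate import SimConfig, simulate_cohort

from conftest import make_call


def _trio_calls(proband, mother, father):
    return (
        make_call(sample_id="P", allele_bp=proband),
        make_call(sample_id="M", allele_bp=mother),
        make_call(sample_id="F", allele_bp=father),
    )


@pytest.fixture
def loc():
    return StrLocus("1", 100, "CA", 20)


def test_expansion_beyond_twice_the_longest_parental_allele(loc):
    p, m, f = _trio_calls((20, 41), (20, 20), (18, 19))
    [ev] = detect_denovo(p, m, f, loc, "F1")
    assert ev.type == "expansion"
    assert ev.proband_allele_bp == 41
    assert ev.parental_extreme_bp == 20
    assert ev.fold == pytest.approx(2.05)


def test_exactly_twice_is_not_an_event(loc):
    p, m, f = _trio_calls((20, 40), (20, 20), (18, 19))
    assert detect_denovo(p, m, f, loc, "F1") == []


def test_contraction_below_half_the_shortest_parental_allele(loc):
    p, m, f = _trio_calls((4, 12), (11, 12), (10, 12))
    [ev] = detect_denovo(p, m, f, loc, "F1")
    assert ev.type == "contraction"
    assert ev.proband_allele_bp == 4
    assert ev.parental_extreme_bp == 10
    assert ev.fold == pytest.approx(2.5)


def test_exactly_half_is_not_a_contraction(loc):
    p, m, f = _trio_calls((5, 12), (11, 12), (10, 12))
    assert detect_denovo(p, m, f, loc, "F1") == []


def test_expansion_and_contraction_can_cooccur(loc):
    p, m, f = _trio_calls((4, 50), (11, 12), (10, 12))
    events = {e.type for e in detect_denovo(p, m, f, loc, "F1")}
    assert events == {"expansion", "contraction"}


def test_swapping_parents_changes_nothing(loc):
    p, m, f = _trio_calls((20, 41), (20, 20), (18, 19))
    a = detect_denovo(p, m, f, loc, "F1")
    b = detect_denovo(p, f, m, loc, "F1")
    assert [(e.type, e.fold) for e in a] == [(e.type, e.fold) for e in b]


def test_enlarging_a_parental_allele_only_removes_expansions(loc):
    p = make_call(sample_id="P", allele_bp=(20, 41))
    m = make_call(sample_id="M", allele_bp=(20, 20))
    for grown in (21, 25, 30, 41):
        f = make_call(sample_id="F", allele_bp=(18, grown))
        events = detect_denovo(p, m, f, loc, "F1")
        base_types = [e.type for e in events]
        assert base_types in ([], ["expansion"])
        if grown > 20:
            # 41 > 2*grown only while grown < 20.5
            assert events == []


def test_missing_member_skips_locus(loc):
    p = make_call(sample_id="P", allele_bp=(20, 41))
    m = make_call(sample_id="M", missing=True)
    f = make_call(sample_id="F", allele_bp=(18, 19))
    assert detect_denovo(p, m, f, loc, "F1") == []


# ---------------------------------------------------------------------------
# cohort scan


def test_pure_mendelian_transmission_yields_no_events():
    cfg = SimConfig(seed=31, n_loci=300, group_sizes={}, n_trios=20,
                    trio_groups=["EUR"], denovo_rate=0.0)
    c = simulate_cohort(cfg)
    from strpop.vcf_io import Pedigree

    trios = Pedigree(c.samples).trios()
    result = scan_trios(c.calls_by_locus(), trios)
    assert result.events == []
    assert c.truth.denovo_events == []


def test_stepwise_mutations_are_invisible_to_the_2x_rule():
    cfg = SimConfig(seed=32, n_loci=400, group_sizes={}, n_trios=20,
                    trio_groups=["EUR"], denovo_rate=5e-3, denovo_mode="stepwise")
    c = simulate_cohort(cfg)
    from strpop.vcf_io import Pedigree

    trios = Pedigree(c.samples).trios()
    result = scan_trios(c.calls_by_locus(), trios)
    assert len(c.truth.stepwise_events) > 0
    assert result.events == []


def test_injected_jumps_recovered_exactly_with_counts_conserved():
    cfg = SimConfig(seed=33, n_loci=500, group_sizes={}, n_trios=25,
                    trio_groups=["EUR"], denovo_rate=3e-3)
    c = simulate_cohort(cfg)
    from strpop.vcf_io import Pedigree

    trios = Pedigree(c.samples).trios()
    result = scan_trios(c.calls_by_locus(), trios)
    got = {(e.family_id, e.locus.chrom, e.locus.pos, e.type) for e in result.events}
    want = {(t["family"], t["chrom"], t["pos"], t["type"]) for t in c.truth.denovo_events}
    assert got == want
    n_exp = sum(result.expansions_per_proband.values())
    n_con = sum(result.contractions_per_proband.values())
    assert n_exp + n_con == len(result.events)


def test_scan_matches_brute_force_per_locus_oracle(small_cohort):
    from strpop.vcf_io import Pedigree

    c = small_cohort
    trios = Pedigree(c.samples).trios()
    calls = c.calls_by_locus()
    result = scan_trios(calls, trios)
    brute = []
    for locus, cs in calls.items():
        by_id = {x.sample_id: x for x in cs}
        for p, m, f in trios:
            pc, mc, fc = by_id[p.sample_id], by_id[m.sample_id], by_id[f.sample_id]
            if pc.missing or mc.missing or fc.missing:
                continue
            if max(pc.allele_bp) > 2 * max(max(mc.allele_bp), max(fc.allele_bp)):
                brute.append((p.family_id, locus.pos, "expansion"))
            if min(pc.allele_bp) < 0.5 * min(min(mc.allele_bp), min(fc.allele_bp)):
                brute.append((p.family_id, locus.pos, "contraction"))
    assert sorted((e.family_id, e.locus.pos, e.type) for e in result.events) == sorted(brute)


# ---------------------------------------------------------------------------
# parental-age summary


def _proband(sid, m_age, f_age):
    return Sample(sample_id=sid, family_id=sid, role="proband",
                  maternal_age_years=m_age, paternal_age_years=f_age)


def test_constant_counts_give_undefined_correlation():
    samples = [_proband(f"P{i}", 30 + i, 32 + i) for i in range(5)]
    out = parental_age_summary({f"P{i}": 7 for i in range(5)}, samples)
    assert not out["maternal"]["defined"]
    assert out["maternal"]["reason"] == "zero variance"


def test_perfect_dependence_gives_r_of_one():
    samples = [_proband(f"P{i}", 20.0 + i, 25.0 + i) for i in range(6)]
    counts = {f"P{i}": 20 + i for i in range(6)}
    out = parental_age_summary(counts, samples)
    assert out["maternal"]["r"] == pytest.approx(1.0)
    assert out["paternal"]["r"] == pytest.approx(1.0)


def test_too_few_probands_is_reported_undefined():
    samples = [_proband("P0", 30, 32)]
    out = parental_age_summary({"P0": 3}, samples)
    assert not out["maternal"]["defined"]
    assert out["maternal"]["n"] == 1


def test_independent_ages_mostly_stay_in_the_null_band():
    """Counts independent of age: |r| below the 95% null bound in >= 80% of
    seeded replicates."""
    rng = np.random.default_rng(34)
    n = 50
    bound = 1.96 / math.sqrt(n)
    inside = 0
    reps = 25
    for _ in range(reps):
        samples = [
            _proband(f"P{i}", float(rng.uniform(20, 45)), float(rng.uniform(22, 50)))
            for i in range(n)
        ]
        counts = {f"P{i}": int(rng.poisson(17)) for i in range(n)}
        out = parental_age_summary(counts, samples)
        inside += abs(out["maternal"]["r"]) < bound
    assert inside >= 0.8 * reps
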