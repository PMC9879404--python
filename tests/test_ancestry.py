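"""Supervised admixture estimation, ancestry assignment, panel curation."""
import itertools

import numpy as np
import pytest

from strpop.ancestry import (
    AdmixtureError,
    AimPanel,
    assign_ancestry,
    estimate_admixture,
    loglik,
    panel_frequencies,
    prune_reference_panel,
)
from strpop.model import AdmixtureVector, SUPERPOPS
from strpop.simulate import simulate_aim_individual, simulate_aim_panel


def grid_search_admixture(dosages, panel, resolution=0.01):
    """Brute-force ML over the 3-simplex at fixed resolution (oracle)."""
    n = int(round(1.0 / resolution))
    points = []
    for i, j, k in itertools.product(range(n + 1), repeat=3):
        if i + j + k <= n:
            points.append((i, j, k, n - i - j - k))
    grid = np.array(points, dtype=float) / n
    ok = ~np.isnan(dosages)
    g = dosages[ok]
    f = panel.freqs[ok]
    p = np.clip(grid @ f.T, 1e-12, 1 - 1e-12)  # (P, n_markers)
    ll = (g * np.log(p) + (2.0 - g) * np.log1p(-p)).sum(axis=1)
    best = int(np.argmax(ll))
    return grid[best], float(ll[best])


@pytest.fixture(scope="module")
def panel():
    return simulate_aim_panel(np.random.default_rng(100), 250)


def test_pure_ancestry_is_recovered(panel):
    """Genotypes drawn from AFR frequencies give q_AFR >= 0.95."""
    rng = np.random.default_rng(1)
    g = simulate_aim_individual((1.0, 0.0, 0.0, 0.0), panel, rng)
    vec = estimate_admixture(g, panel)
    assert vec.q[0] >= 0.95
    assert vec.n_markers_used == 250


def test_flat_panel_is_flagged_non_identifiable():
    freqs = np.full((50, 4), 0.4)
    panel = AimPanel(positions=[str(i) for i in range(50)], freqs=freqs)
    g = np.random.default_rng(2).binomial(2, 0.4, size=50).astype(float)
    vec = estimate_admixture(g, panel)
    assert vec.non_identifiable
    assert vec.q == pytest.approx((0.25, 0.25, 0.25, 0.25))


def test_em_matches_grid_search_oracle_loglik():
    """EM log-likelihood reaches the 0.01-resolution simplex grid optimum."""
    rng = np.random.default_rng(3)
    panel = simulate_aim_panel(rng, 40)
    for trial in range(3):
        q_true = rng.dirichlet([1, 1, 1, 1])
        g = simulate_aim_individual(q_true, panel, rng)
        vec = estimate_admixture(g, panel)
        _, ll_grid = grid_search_admixture(g, panel)
        assert vec.loglik >= ll_grid - 1e-6


def test_balanced_two_way_admixture_recovery(panel):
    """50/50 EUR-EAS mixtures are recovered within 0.15 (median of 100)."""
    rng = np.random.default_rng(4)
    errs_eur, errs_eas = [], []
    for _ in range(100):
        g = simulate_aim_individual((0.0, 0.5, 0.5, 0.0), panel, rng)
        vec = estimate_admixture(g, panel)
        errs_eur.append(abs(vec.q[1] - 0.5))
        errs_eas.append(abs(vec.q[2] - 0.5))
    assert np.median(errs_eur) <= 0.15
    assert np.median(errs_eas) <= 0.15


def test_error_recovery_improves_with_marker_count():
    rng = np.random.default_rng(5)
    maes = {}
    for n_markers in (50, 250):
        panel = simulate_aim_panel(np.random.default_rng(50), n_markers)
        errs = []
        for _ in range(60):
            q = rng.dirichlet([1, 1, 1, 1])
            g = simulate_aim_individual(q, panel, rng)
            errs.append(np.abs(np.array(estimate_admixture(g, panel).q) - q).mean())
        maes[n_markers] = np.mean(errs)
    assert maes[250] < maes[50]


def test_simplex_invariants_on_random_inputs():
    rng = np.random.default_rng(6)
    for _ in range(25):
        n = int(rng.integers(5, 120))
        panel = simulate_aim_panel(rng, n)
        g = rng.integers(0, 3, size=n).astype(float)
        g[rng.random(n) < 0.1] = np.nan
        if np.all(np.isnan(g)):
            continue
        vec = estimate_admixture(g, panel)
        assert min(vec.q) >= 0.0
        assert sum(vec.q) == pytest.approx(1.0, abs=1e-9)
        # estimate is at least as good as the uniform start
        ok = ~np.isnan(g)
        assert vec.loglik >= loglik(np.full(4, 0.25), g[ok], panel.freqs[ok]) - 1e-9


def test_population_permutation_permutes_q(panel):
    rng = np.random.default_rng(7)
    g = simulate_aim_individual((0.6, 0.1, 0.2, 0.1), panel, rng)
    vec = estimate_admixture(g, panel)
    perm = [2, 0, 3, 1]
    panel_p = AimPanel(positions=panel.positions, freqs=panel.freqs[:, perm])
    vec_p = estimate_admixture(g, panel_p)
    assert np.allclose(np.array(vec.q)[perm], vec_p.q, atol=1e-6)


def test_zero_overlap_raises(panel):
    with pytest.raises(AdmixtureError):
        estimate_admixture(np.full(250, np.nan), panel)


# ---------------------------------------------------------------------------
# assignment rules


def _vec(q):
    return AdmixtureVector(q=q, n_markers_used=250, loglik=0.0)


@pytest.mark.parametrize(
    "q,self_report,primary,secondary",
    [
        ((0.10, 0.80, 0.05, 0.05), None, "EUR", None),
        ((0.10, 0.09, 0.05, 0.76), None, "NonadmixedAMR", None),
        ((0.05, 0.20, 0.05, 0.70), None, "AdmixedAMR", None),
        ((0.55, 0.40, 0.03, 0.02), None, "AFR", "EUR"),
        ((0.60, 0.35, 0.03, 0.02), None, "AFR", "EUR"),  # 0.60 exactly: secondary rule
        ((0.45, 0.40, 0.10, 0.05), None, "unassigned", None),
        ((0.10, 0.45, 0.40, 0.05), "Pacific Islander", "PAC", None),
        ((0.05, 0.90, 0.03, 0.02), "pacific islander", "PAC", None),
    ],
)
def test_assignment_rules(q, self_report, primary, secondary):
    a = assign_ancestry(_vec(q), self_report)
    assert a.primary == primary
    assert a.secondary == secondary


def test_argmax_tie_broken_by_fixed_population_order():
    a = assign_ancestry(_vec((0.45, 0.45, 0.05, 0.05)))
    assert a.primary == "unassigned"
    a = assign_ancestry(_vec((0.61, 0.29, 0.05, 0.05)))
    assert a.primary == "AFR"


# ---------------------------------------------------------------------------
# panel curation


def _reference_set(rng, panel, sizes, admixed_eur_fraction=0.0):
    dosages, labels = [], []
    pure = {p: tuple(1.0 if x == p else 0.0 for x in SUPERPOPS) for p in SUPERPOPS}
    for pop, n in sizes.items():
        n_admixed = int(round(admixed_eur_fraction * n)) if pop == "EUR" else 0
        for i in range(n):
            if i < n_admixed:
                q = (0.0, 0.5, 0.0, 0.5)  # EUR/AMR admixed mislabeled as EUR
            else:
                q = pure[pop]
            dosages.append(simulate_aim_individual(q, panel, rng))
            labels.append(pop)
    return np.array(dosages), labels


def test_clean_panel_reaches_fixed_point_without_evictions(panel):
    rng = np.random.default_rng(8)
    dosages, labels = _reference_set(rng, panel, {p: 20 for p in SUPERPOPS})
    _, report = prune_reference_panel(
        dosages, labels, panel.positions, own_fraction_threshold=0.5, seed=0
    )
    assert report.evicted == []
    assert report.n_iterations == 1


def test_oversized_population_downsampled_to_300():
    rng = np.random.default_rng(9)
    panel = simulate_aim_panel(rng, 60)
    sizes = {"AFR": 30, "EUR": 600, "EAS": 30, "AMR": 30}
    dosages, labels = _reference_set(rng, panel, sizes)
    _, report = prune_reference_panel(
        dosages, labels, panel.positions, max_per_pop=300, own_fraction_threshold=0.5, seed=1
    )
    assert report.per_pop_sizes["EUR"] == 300
    assert report.per_pop_sizes["AFR"] == 30


def test_admixed_members_are_evicted_pure_members_kept():
    """10% EUR/AMR admixed individuals mislabeled EUR are all evicted at a
    0.75 own-fraction threshold; no pure member is evicted (median of 5 seeds)."""
    outcomes = []
    for seed in range(5):
        rng = np.random.default_rng(200 + seed)
        panel = simulate_aim_panel(rng, 120)
        dosages, labels = _reference_set(
            rng, panel, {p: 40 for p in SUPERPOPS}, admixed_eur_fraction=0.10
        )
        admixed_idx = {i for i, l in enumerate(labels) if l == "EUR"} & set(range(40, 44))
        # admixed members are the first 4 EUR rows; EUR block starts after AFR
        eur_start = labels.index("EUR")
        admixed_idx = set(range(eur_start, eur_start + 4))
        _, report = prune_reference_panel(
            dosages, labels, panel.positions, own_fraction_threshold=0.75, seed=seed
        )
        evicted = set(report.evicted)
        outcomes.append(
            (len(admixed_idx & evicted) == 4, len(evicted - admixed_idx) == 0)
        )
    all_evicted = [a for a, _ in outcomes]
    no_pure = [b for _, b in outcomes]
    assert np.median(all_evicted) == 1.0
    assert np.median(no_pure) == 1.0


def test_eviction_emptying_a_population_is_an_error(panel):
    rng = np.random.default_rng(10)
    dosages, labels = _reference_set(rng, panel, {p: 10 for p in SUPERPOPS})
    # no member can reach an own-fraction of 1.0 (frequencies are clamped away
    # from 0/1), so the first iteration would evict an entire population
    with pytest.raises(AdmixtureError):
        prune_reference_panel(
            dosages, labels, panel.positions, own_fraction_threshold=1.0, seed=0
        )


def test_panel_frequencies_are_clamped():
    dosages = np.zeros((8, 5))
    labels = ["AFR", "AFR", "EUR", "EUR", "EAS", "EAS", "AMR", "AMR"]
    freqs = panel_frequencies(dosages, labels)
    assert freqs.min() > 0 and freqs.max() < 1
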