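"""Supervised 4-way admixture estimation from ancestry-informative markers.

Model: at biallelic marker *i* an individual's alternate-allele dosage is
g_i ~ Binomial(2, p_i) with p_i = sum_k q_k f_ki, where f_ki is the
alternate-allele frequency of superpopulation k (AFR, EUR, EAS, AMR) and q is
the admixture vector on the 3-simplex. q is estimated by maximum likelihood
via EM with a fixed uniform initialization, so the result is deterministic
for fixed input. Reference panels are curated by iterative eviction of
admixed members followed by seeded downsampling.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import AdmixtureVector, AncestryAssignment, SUPERPOPS

log = logging.getLogger(__name__)

FREQ_CLAMP_EPS = 1e-3


class AdmixtureError(ValueError):
    pass


@dataclass
class AimPanel:
    """Reference allele frequencies at AIM positions for the 4 superpopulations."""

    positions: list[str]
    freqs: np.ndarray  # (n_markers, 4), columns in SUPERPOPS order
    pops: tuple[str, ...] = SUPERPOPS

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.pops):
            raise AdmixtureError(
                f"panel needs one frequency column per population, got shape {self.freqs.shape}"
            )
        if len(self.pops) < 4:
            raise AdmixtureError(f"panel needs >= 4 populations, got {self.pops}")
        if self.freqs.shape[0] != len(self.positions):
            raise AdmixtureError("positions and frequency rows disagree")
        self.freqs = np.clip(self.freqs, FREQ_CLAMP_EPS, 1.0 - FREQ_CLAMP_EPS)

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.freqs, columns=[f"f_{p}" for p in self.pops])
        df.insert(0, "position", self.positions)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AimPanel":
        df = pd.read_csv(path, sep="\t")
        cols = [f"f_{p}" for p in SUPERPOPS]
        return cls(positions=list(df["position"].astype(str)), freqs=df[cols].to_numpy())


def loglik(q: np.ndarray, dosages: np.ndarray, freqs: np.ndarray) -> float:
    """Binomial-mixture log-likelihood of admixture q given dosage vector."""
    p = freqs @ q
    return float(np.sum(dosages * np.log(p) + (2.0 - dosages) * np.log1p(-p)))


def estimate_admixture(
    genotypes: Sequence[float] | np.ndarray,
    panel: AimPanel,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> AdmixtureVector:
    """Maximum-likelihood admixture via EM from a uniform start.

    ``genotypes`` are alternate-allele dosages in {0, 1, 2}, aligned with
    ``panel.positions``; NaN marks a missing genotype and is skipped.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape != (panel.n_markers,):
        raise AdmixtureError(
            f"genotypes length {g.shape} does not match panel of {panel.n_markers} markers"
        )
    ok = ~np.isnan(g)
    g = g[ok]
    f = panel.freqs[ok]
    n = g.size
    if n == 0:
        raise AdmixtureError("no non-missing genotypes overlap the panel")
    k = f.shape[1]
    if np.ptp(f, axis=1).max() < 1e-12:
        # All populations identical at every marker: likelihood is flat in q.
        q = np.full(k, 1.0 / k)
        return AdmixtureVector(
            q=tuple(q), n_markers_used=n, loglik=loglik(q, g, f), non_identifiable=True
        )
    q = np.full(k, 1.0 / k)
    ll = loglik(q, g, f)
    for _ in range(max_iter):
        p = f @ q  # (n,)
        # responsibilities: alt copies from pop k, and ref copies from pop k
        alt = q * f / p[:, None]            # (n, k)
        ref = q * (1.0 - f) / (1.0 - p)[:, None]
        counts = (g[:, None] * alt + (2.0 - g)[:, None] * ref).sum(axis=0)
        q_new = counts / (2.0 * n)
        q_new = np.clip(q_new, 0.0, None)
        q_new /= q_new.sum()
        ll_new = loglik(q_new, g, f)
        q = q_new
        if ll_new - ll < tol:
            ll = ll_new
            break
        ll = ll_new
    return AdmixtureVector(q=tuple(q), n_markers_used=n, loglik=ll)


# Assignment rules, applied in order:
#   1. Pacific Islander self-report wins (no PAC reference population exists).
#   2. q_AMR > 0.75 -> NonadmixedAMR.
#   3. max component > 0.60 -> that population (AMR -> AdmixedAMR).
#   4. max component in [0.50, 0.60] -> primary = argmax, secondary = runner-up.
#   5. otherwise unassigned.
PAC_SELF_REPORTS = {"pacific islander", "pac"}


def assign_ancestry(
    admixture: AdmixtureVector, self_report: Optional[str] = None
) -> AncestryAssignment:
    if self_report is not None and self_report.strip().lower() in PAC_SELF_REPORTS:
        return AncestryAssignment(primary="PAC")
    q = np.asarray(admixture.q)
    # ties broken by fixed population order (AFR, EUR, EAS, AMR)
    imax = int(np.argmax(q))
    qmax = q[imax]
    if q[SUPERPOPS.index("AMR")] > 0.75:
        return AncestryAssignment(primary="NonadmixedAMR")
    label = "AdmixedAMR" if SUPERPOPS[imax] == "AMR" else SUPERPOPS[imax]
    if qmax > 0.60:
        return AncestryAssignment(primary=label)
    if qmax >= 0.50:
        rest = q.copy()
        rest[imax] = -1.0
        second = SUPERPOPS[int(np.argmax(rest))]
        return AncestryAssignment(primary=label, secondary=second)
    return AncestryAssignment(primary="unassigned")


def panel_frequencies(
    dosages: np.ndarray, labels: Sequence[str], pops: Sequence[str] = SUPERPOPS
) -> np.ndarray:
    """Per-population alternate-allele frequencies from labeled reference dosages.

    ``dosages``: (n_individuals, n_markers), NaN = missing.
    """
    labels = np.asarray(labels)
    out = np.empty((dosages.shape[1], len(pops)))
    for j, pop in enumerate(pops):
        sub = dosages[labels == pop]
        if sub.size == 0:
            raise AdmixtureError(f"population {pop} has no members")
        with np.errstate(invalid="ignore"):
            out[:, j] = np.nanmean(sub, axis=0) / 2.0
    out = np.nan_to_num(out, nan=0.5)
    return np.clip(out, FREQ_CLAMP_EPS, 1.0 - FREQ_CLAMP_EPS)


@dataclass
class PanelCurationReport:
    n_iterations: int
    evicted: list[int]
    kept: list[int]
    per_pop_sizes: dict[str, int]


def prune_reference_panel(
    dosages: np.ndarray,
    labels: Sequence[str],
    positions: Sequence[str],
    max_per_pop: int = 300,
    own_fraction_threshold: float = 0.75,
    max_iterations: int = 10,
    seed: int = 0,
) -> tuple[AimPanel, PanelCurationReport]:
    """Curate a labeled reference set into an AIM panel.

    Iterates: estimate frequencies from current members, estimate each
    member's admixture against them, evict members whose own-label component
    falls below ``own_fraction_threshold``; stops at a fixed point. Surviving
    populations larger than ``max_per_pop`` are downsampled with a seeded RNG
    before the final frequency estimate.
    """
    labels = np.asarray(labels)
    dosages = np.asarray(dosages, dtype=float)
    active = np.arange(dosages.shape[0])
    evicted: list[int] = []
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        freqs = panel_frequencies(dosages[active], labels[active])
        panel = AimPanel(positions=list(positions), freqs=freqs)
        own = np.array(
            [
                estimate_admixture(dosages[i], panel).q[SUPERPOPS.index(labels[i])]
                for i in active
            ]
        )
        bad = own < own_fraction_threshold
        if not bad.any():
            break
        for pop in SUPERPOPS:
            if not ((labels[active] == pop) & ~bad).any():
                raise AdmixtureError(
                    f"eviction at threshold {own_fraction_threshold} emptied population {pop}"
                )
        evicted.extend(active[bad].tolist())
        active = active[~bad]
    rng = np.random.default_rng(seed)
    final: list[int] = []
    for pop in SUPERPOPS:
        members = active[labels[active] == pop]
        if members.size > max_per_pop:
            members = np.sort(rng.choice(members, size=max_per_pop, replace=False))
            log.info("downsampled %s from %d to %d members", pop, (labels[active] == pop).sum(), max_per_pop)
        final.extend(members.tolist())
    final_idx = np.array(sorted(final))
    freqs = panel_frequencies(dosages[final_idx], labels[final_idx])
    report = PanelCurationReport(
        n_iterations=n_iter,
        evicted=sorted(evicted),
        kept=final_idx.tolist(),
        per_pop_sizes={p: int((labels[final_idx] == p).sum()) for p in SUPERPOPS},
    )
    return AimPanel(positions=list(positions), freqs=freqs), report


def read_aim_genotypes(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read an AIM dosage TSV: first column `sample`, one column per position.

    Returns (sample_ids, positions, dosages) with NaN for missing entries.
    """
    df = pd.read_csv(path, sep="\t")
    samples = list(df["sample"].astype(str))
    positions = [c for c in df.columns if c != "sample"]
    return samples, positions, df[positions].to_numpy(dtype=float)


def write_aim_genotypes(
    path: str | Path, sample_ids: Sequence[str], positions: Sequence[str], dosages: np.ndarray
) -> None:
    df = pd.DataFrame(dosages, columns=list(positions))
    df.insert(0, "sample", list(sample_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%g")
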