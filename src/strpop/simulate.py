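"""Synthetic STR cohort generator with ground truth.

Emulates the statistical structure the pipeline assumes: per-ancestry
allele-length distributions (discretized normals over repeat copies, floor 1
copy), Mendelian trio transmission with injected de novo jumps, low-variance
conserved loci, pathogenic expansions at catalog loci, and AIM SNP genotypes
drawn binomially from admixture-weighted Balding-Nichols population
frequencies. Everything derives from one integer seed; with genotyping noise
off (the default) every call passes the quality filters so truth-recovery is
exact.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from .ancestry import AimPanel, write_aim_genotypes
from .model import ANCESTRY_GROUPS, PathogenicLocusRecord, Sample, StrCall, StrLocus, SUPERPOPS
from .vcf_io import write_pedigree, write_str_vcf

_BASES = np.array(list("ACGT"))

# Typical admixture composition per cohort ancestry group, on the
# (AFR, EUR, EAS, AMR) simplex. Pacific Islanders carry no reference
# population of their own and present as a European / East Asian blend,
# identified by self-report.
GROUP_ADMIXTURE = {
    "AFR": (0.90, 0.05, 0.03, 0.02),
    "EUR": (0.03, 0.90, 0.04, 0.03),
    "EAS": (0.02, 0.05, 0.90, 0.03),
    "AdmixedAMR": (0.05, 0.23, 0.06, 0.66),
    "NonadmixedAMR": (0.02, 0.05, 0.03, 0.90),
    "PAC": (0.02, 0.48, 0.48, 0.02),
}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseConfig:
    """Genotyping-noise injections. All fractions are of the total call count
    and the injected sets are disjoint. Everything defaults to zero so that
    simulated cohorts are perfectly genotyped unless noise is requested."""

    missing_rate: float = 0.0
    low_depth_fraction: float = 0.0
    high_depth_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    bad_ci_fraction: float = 0.0
    spanbound_only_fraction: float = 0.0

    def __post_init__(self) -> None:
        fracs = [
            self.missing_rate,
            self.low_depth_fraction,
            self.high_depth_fraction,
            self.low_quality_fraction,
            self.bad_ci_fraction,
            self.spanbound_only_fraction,
        ]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise SimConfigError("noise fractions must be in [0,1]")
        if sum(fracs) > 1.0:
            raise SimConfigError("noise fractions sum to more than 1")

    @property
    def total(self) -> float:
        return (
            self.missing_rate
            + self.low_depth_fraction
            + self.high_depth_fraction
            + self.low_quality_fraction
            + self.bad_ci_fraction
            + self.spanbound_only_fraction
        )


@dataclass(frozen=True)
class DivergentInjection:
    """Shift one group's mean at ``n_loci`` loci by ``shift_sd`` population
    SDs and at least ``pct_shift`` of the base mean (whichever is larger)."""

    group: str
    n_loci: int
    shift_sd: float = 8.0
    pct_shift: float = 0.30


@dataclass(frozen=True)
class ConservedInjection:
    """Create ``n_loci`` low-variance loci (target coefficient of variation)
    and give ``n_carriers`` probands one ``expansion_ratio`` x mean allele."""

    n_loci: int
    target_cov: float = 0.03
    n_carriers: int = 1
    expansion_ratio: float = 3.0


@dataclass(frozen=True)
class PathogenicInjection:
    """Give ``n_carriers`` probands an ``allele_copies`` allele at the
    catalog locus of ``gene``."""

    gene: str
    n_carriers: int
    allele_copies: int


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_loci: int = 1000
    group_sizes: dict = field(
        default_factory=lambda: {g: 100 for g in ANCESTRY_GROUPS}
    )
    n_trios: int = 50
    trio_groups: Optional[Sequence[str]] = None  # default: cycle ANCESTRY_GROUPS
    mean_copies_range: tuple[float, float] = (8.0, 30.0)
    cov_copies_range: tuple[float, float] = (0.05, 0.15)
    divergent: tuple[DivergentInjection, ...] = ()
    conserved: Optional[ConservedInjection] = None
    pathogenic: tuple[PathogenicInjection, ...] = ()
    pathogenic_catalog: tuple[PathogenicLocusRecord, ...] = ()
    denovo_rate: float = 0.0
    denovo_jump_factor: float = 2.5
    denovo_contraction_fraction: float = 0.1
    denovo_mode: str = "jump"  # "jump" | "stepwise"
    n_aim_markers: int = 250
    fst: float = 0.5
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.denovo_rate <= 1.0:
            raise SimConfigError("denovo_rate must be in [0,1]")
        if self.denovo_mode == "jump" and self.denovo_jump_factor <= 1.0:
            raise SimConfigError("expansion jump factor must exceed 1")
        if self.conserved is not None:
            lo = self.mean_copies_range[0]
            # target cov must be representable after integer rounding noise
            if self.conserved.target_cov * lo < 0.0:
                raise SimConfigError("infeasible conserved target cov")
        for inj in self.divergent:
            if inj.group not in ANCESTRY_GROUPS:
                raise SimConfigError(f"unknown group {inj.group}")
        for g in self.group_sizes:
            if g not in ANCESTRY_GROUPS:
                raise SimConfigError(f"unknown group {g}")


@dataclass
class TruthTable:
    divergent_loci: list = field(default_factory=list)      # {chrom,pos,repeat_unit,group}
    conserved_loci: list = field(default_factory=list)      # {chrom,pos,repeat_unit}
    conserved_carriers: list = field(default_factory=list)  # {sample,chrom,pos,repeat_unit,allele_bp}
    pathogenic_carriers: list = field(default_factory=list) # {sample,gene,allele_bp}
    denovo_events: list = field(default_factory=list)       # {family,chrom,pos,repeat_unit,type,factor}
    stepwise_events: list = field(default_factory=list)
    true_admixture: dict = field(default_factory=dict)      # sample -> [q_AFR..q_AMR]
    true_group: dict = field(default_factory=dict)          # sample -> group
    noise_injections: dict = field(default_factory=dict)    # reason -> count

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    config: SimConfig
    samples: list[Sample]
    loci: list[StrLocus]
    copies: np.ndarray       # (L, S, 2) int32
    allele_bp: np.ndarray    # (L, S, 2) int32
    depth: np.ndarray        # (L, S) int32
    quality: np.ndarray      # (L, S) float32
    ci_lo_bp: np.ndarray     # (L, S, 2) int32
    ci_hi_bp: np.ndarray     # (L, S, 2) int32
    read_counts: np.ndarray  # (L, S, 4) int16
    missing: np.ndarray      # (L, S) bool
    aim_positions: list[str]
    aim_dosages: np.ndarray  # (S, M) float
    panel: AimPanel
    truth: TruthTable

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def calls_at(self, locus_index: int) -> list[StrCall]:
        out = []
        for j, sid in enumerate(self.sample_ids):
            if self.missing[locus_index, j]:
                out.append(StrCall(sample_id=sid, allele_bp=None, ci_bp=None, missing=True))
                continue
            a = tuple(int(v) for v in self.allele_bp[locus_index, j])
            ci = (
                (int(self.ci_lo_bp[locus_index, j, 0]), int(self.ci_hi_bp[locus_index, j, 0])),
                (int(self.ci_lo_bp[locus_index, j, 1]), int(self.ci_hi_bp[locus_index, j, 1])),
            )
            out.append(
                StrCall(
                    sample_id=sid,
                    allele_bp=a,
                    ci_bp=ci,
                    depth=int(self.depth[locus_index, j]),
                    quality=float(self.quality[locus_index, j]),
                    read_counts=tuple(int(v) for v in self.read_counts[locus_index, j]),
                )
            )
        return out

    def iter_calls(self) -> Iterator[tuple[StrLocus, list[StrCall]]]:
        for i, locus in enumerate(self.loci):
            yield locus, self.calls_at(i)

    def calls_by_locus(self) -> dict[StrLocus, list[StrCall]]:
        return dict(self.iter_calls())

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the pipeline's input files; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "pedigree": outdir / "pedigree.tsv",
            "aim_genotypes": outdir / "aim_genotypes.tsv",
            "panel": outdir / "panel.tsv",
            "truth": outdir / "truth.json",
        }
        write_str_vcf(paths["vcf"], self.iter_calls(), self.sample_ids)
        write_pedigree(paths["pedigree"], self.samples)
        write_aim_genotypes(paths["aim_genotypes"], self.sample_ids, self.aim_positions, self.aim_dosages)
        self.panel.to_tsv(paths["panel"])
        self.truth.to_json(paths["truth"])
        return paths


def simulate_aim_panel(rng: np.random.Generator, n_markers: int = 250, fst: float = 0.5) -> AimPanel:
    """Balding-Nichols panel: ancestral frequency p ~ U(0.1, 0.9), population
    frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F), independently per population."""
    p = rng.uniform(0.1, 0.9, size=n_markers)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    freqs = rng.beta(a[:, None], b[:, None], size=(n_markers, len(SUPERPOPS)))
    positions = [f"AIM{i + 1:04d}" for i in range(n_markers)]
    return AimPanel(positions=positions, freqs=freqs)


def simulate_aim_individual(q: Sequence[float], panel: AimPanel, rng: np.random.Generator) -> np.ndarray:
    """Dosage vector: per marker, alt copies ~ Binomial(2, sum_k q_k f_k)."""
    q = np.asarray(q, dtype=float)
    if q.min() < -1e-12 or abs(q.sum() - 1.0) > 1e-9:
        raise SimConfigError(f"admixture must lie on the simplex, got {q}")
    p = panel.freqs @ q
    return rng.binomial(2, p).astype(float)


def _random_unit(rng: np.random.Generator) -> str:
    period = int(rng.integers(1, 7))
    return "".join(rng.choice(_BASES, size=period))


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()

    # ------------------------------------------------------------------ samples
    samples: list[Sample] = []
    group_of: list[str] = []
    for g in ANCESTRY_GROUPS:
        for i in range(config.group_sizes.get(g, 0)):
            sid = f"{g}_S{i + 1:04d}"
            samples.append(
                Sample(
                    sample_id=sid,
                    family_id=f"{g}_F{i + 1:04d}",
                    role="proband",
                    self_reported_ancestry="Pacific Islander" if g == "PAC" else None,
                )
            )
            group_of.append(g)
    trio_groups = list(config.trio_groups) if config.trio_groups else list(ANCESTRY_GROUPS)
    trio_members: list[tuple[int, int, int, str]] = []  # (proband_idx, mother_idx, father_idx, group)
    for t in range(config.n_trios):
        g = trio_groups[t % len(trio_groups)]
        fam = f"TRIO{t + 1:04d}"
        m_age = float(np.clip(rng.normal(33.0, 5.0), 18.0, 50.0))
        f_age = float(np.clip(rng.normal(35.0, 6.0), 18.0, 60.0))
        base = len(samples)
        sra = "Pacific Islander" if g == "PAC" else None
        samples.append(
            Sample(
                sample_id=f"{fam}_P", family_id=fam, role="proband",
                father_id=f"{fam}_F", mother_id=f"{fam}_M",
                self_reported_ancestry=sra,
                maternal_age_years=round(m_age, 1), paternal_age_years=round(f_age, 1),
            )
        )
        samples.append(Sample(sample_id=f"{fam}_M", family_id=fam, role="mother",
                              self_reported_ancestry=sra))
        samples.append(Sample(sample_id=f"{fam}_F", family_id=fam, role="father",
                              self_reported_ancestry=sra))
        group_of.extend([g, g, g])
        trio_members.append((base, base + 1, base + 2, g))
    n_samples = len(samples)
    sample_ids = [s.sample_id for s in samples]
    truth.true_group = dict(zip(sample_ids, group_of))

    # ------------------------------------------------------------------- loci
    n_base = config.n_loci
    n_cons = config.conserved.n_loci if config.conserved else 0
    path_records = list(config.pathogenic_catalog) if config.pathogenic else []
    loci: list[StrLocus] = []
    periods = np.empty(n_base + n_cons + len(path_records), dtype=np.int32)
    for i in range(n_base + n_cons):
        unit = _random_unit(rng)
        mean_c = rng.uniform(*config.mean_copies_range)
        loci.append(
            StrLocus(
                chrom=str(1 + i % 22),
                pos=10_000 + i,
                repeat_unit=unit,
                ref_len_bp=max(1, int(round(mean_c)) * len(unit)),
            )
        )
        periods[i] = len(unit)
    for rec in path_records:
        loci.append(rec.locus)
        periods[len(loci) - 1] = rec.locus.period
    n_loci = len(loci)

    # base per-locus distributions over repeat copies
    mean_c = rng.uniform(*config.mean_copies_range, size=n_loci)
    sd_c = mean_c * rng.uniform(*config.cov_copies_range, size=n_loci)
    cons_idx = np.arange(n_base, n_base + n_cons)
    if config.conserved:
        tgt = config.conserved.target_cov
        mean_c[cons_idx] = rng.uniform(10.0, 20.0, size=n_cons)
        # integer rounding adds ~1/12 variance; subtract it from the target
        sd_c[cons_idx] = np.sqrt(np.maximum((tgt * mean_c[cons_idx]) ** 2 - 1.0 / 12.0, 0.0))
        for i in cons_idx:
            truth.conserved_loci.append(
                {"chrom": loci[i].chrom, "pos": loci[i].pos, "repeat_unit": loci[i].repeat_unit}
            )
    gene_locus_idx = {}
    for j, rec in enumerate(path_records):
        i = n_base + n_cons + j
        gene_locus_idx[rec.gene] = i
        mean_c[i] = rec.locus.ref_len_bp / rec.locus.period
        sd_c[i] = 0.05 * mean_c[i]

    # per-group means: divergent injections shift one group at chosen loci
    group_idx = {g: k for k, g in enumerate(ANCESTRY_GROUPS)}
    group_means = np.tile(mean_c[:, None], (1, len(ANCESTRY_GROUPS)))
    injectable = list(range(n_base))
    rng.shuffle(injectable)
    cursor = 0
    for inj in config.divergent:
        take = injectable[cursor : cursor + inj.n_loci]
        if len(take) < inj.n_loci:
            raise SimConfigError("not enough base loci for divergent injections")
        cursor += inj.n_loci
        k = group_idx[inj.group]
        for i in take:
            shifted = max(mean_c[i] * (1.0 + inj.pct_shift), mean_c[i] + inj.shift_sd * sd_c[i])
            group_means[i, k] = shifted
            truth.divergent_loci.append(
                {
                    "chrom": loci[i].chrom,
                    "pos": loci[i].pos,
                    "repeat_unit": loci[i].repeat_unit,
                    "group": inj.group,
                }
            )

    # ---------------------------------------------------------------- alleles
    sample_group_idx = np.array([group_idx[g] for g in group_of])
    means = group_means[:, sample_group_idx]  # (L, S)
    copies = np.rint(rng.normal(means[:, :, None], sd_c[:, None, None], size=(n_loci, n_samples, 2)))
    copies = np.maximum(copies, 1.0).astype(np.int32)

    # trio probands: Mendelian inheritance overwrites the independent draw
    for p_idx, m_idx, f_idx, _g in trio_members:
        pick_m = rng.integers(0, 2, size=n_loci)
        pick_f = rng.integers(0, 2, size=n_loci)
        rows = np.arange(n_loci)
        copies[:, p_idx, 0] = copies[rows, m_idx, pick_m]
        copies[:, p_idx, 1] = copies[rows, f_idx, pick_f]

    # de novo injections
    if config.denovo_rate > 0:
        for p_idx, m_idx, f_idx, _g in trio_members:
            fam = samples[p_idx].family_id
            hit_loci = np.nonzero(rng.random(n_loci) < config.denovo_rate)[0]
            for i in hit_loci:
                if config.denovo_mode == "stepwise":
                    a = int(rng.integers(0, 2))
                    step = 1 if rng.random() < 0.5 else -1
                    copies[i, p_idx, a] = max(1, copies[i, p_idx, a] + step)
                    truth.stepwise_events.append(
                        {"family": fam, "chrom": loci[i].chrom, "pos": loci[i].pos,
                         "repeat_unit": loci[i].repeat_unit, "step": step}
                    )
                    continue
                parent_max = int(max(copies[i, m_idx].max(), copies[i, f_idx].max()))
                parent_min = int(min(copies[i, m_idx].min(), copies[i, f_idx].min()))
                contraction = (
                    rng.random() < config.denovo_contraction_fraction
                    and math.floor(0.4 * parent_min) >= 1
                )
                if contraction:
                    new = math.floor(0.4 * parent_min)
                    copies[i, p_idx, :] = new  # both alleles shrink so the min rule sees it
                    ev_type, factor = "contraction", parent_min / new
                else:
                    new = math.ceil(config.denovo_jump_factor * parent_max)
                    copies[i, p_idx, int(rng.integers(0, 2))] = new
                    ev_type, factor = "expansion", new / parent_max
                truth.denovo_events.append(
                    {"family": fam, "chrom": loci[i].chrom, "pos": loci[i].pos,
                     "repeat_unit": loci[i].repeat_unit, "type": ev_type,
                     "factor": round(float(factor), 6)}
                )

    # conserved-locus expansion carriers. Trio probands are preferred because
    # they sit outside the population baseline: at desk-scale cohort sizes a
    # 3x allele inside a ~200-allele baseline would inflate the locus CV past
    # the conservation cutoff, an artifact full-size cohorts do not have.
    if config.conserved and config.conserved.n_carriers > 0:
        carrier_pool = [j for j, s in enumerate(samples)
                        if s.role == "proband" and s.father_id is not None]
        if not carrier_pool:
            carrier_pool = [j for j, s in enumerate(samples) if s.role == "proband"]
        trio_parents = {p: (m, f) for p, m, f, _g in trio_members}
        for i in cons_idx:
            carriers = rng.choice(carrier_pool, size=config.conserved.n_carriers, replace=False)
            for j in carriers:
                allele = int(math.ceil(config.conserved.expansion_ratio * mean_c[i]))
                copies[i, j, int(rng.integers(0, 2))] = allele
                truth.conserved_carriers.append(
                    {"sample": sample_ids[j], "chrom": loci[i].chrom, "pos": loci[i].pos,
                     "repeat_unit": loci[i].repeat_unit,
                     "allele_bp": allele * loci[i].period}
                )
                # a trio proband's injected expansion is also a de novo event
                # whenever it clears the >2x parental rule
                if j in trio_parents:
                    m_idx, f_idx = trio_parents[j]
                    parent_max = int(max(copies[i, m_idx].max(), copies[i, f_idx].max()))
                    if allele > 2 * parent_max:
                        truth.denovo_events.append(
                            {"family": samples[j].family_id, "chrom": loci[i].chrom,
                             "pos": loci[i].pos, "repeat_unit": loci[i].repeat_unit,
                             "type": "expansion",
                             "factor": round(allele / parent_max, 6)}
                        )

    # pathogenic expansion carriers
    if config.pathogenic:
        singleton_idx = [j for j, s in enumerate(samples)
                         if s.role == "proband" and s.father_id is None]
        pool = list(singleton_idx)
        rng.shuffle(pool)
        for inj in config.pathogenic:
            if inj.gene not in gene_locus_idx:
                raise SimConfigError(f"gene {inj.gene} not in pathogenic_catalog")
            i = gene_locus_idx[inj.gene]
            if len(pool) < inj.n_carriers:
                raise SimConfigError("not enough probands for pathogenic carriers")
            carriers, pool = pool[: inj.n_carriers], pool[inj.n_carriers :]
            for j in carriers:
                copies[i, j, int(rng.integers(0, 2))] = inj.allele_copies
                truth.pathogenic_carriers.append(
                    {"sample": sample_ids[j], "gene": inj.gene,
                     "allele_bp": inj.allele_copies * loci[i].period}
                )

    allele_bp = copies * periods[:, None, None]

    # -------------------------------------------------------------- genotyping
    depth = rng.integers(55, 100, size=(n_loci, n_samples)).astype(np.int32)
    quality = np.full((n_loci, n_samples), 0.99, dtype=np.float32)
    ci_lo_bp = np.maximum(allele_bp - periods[:, None, None], periods[:, None, None])
    ci_lo_bp = np.minimum(ci_lo_bp, allele_bp).astype(np.int32)
    ci_hi_bp = (allele_bp + periods[:, None, None]).astype(np.int32)
    read_counts = np.empty((n_loci, n_samples, 4), dtype=np.int16)
    read_counts[..., 0] = rng.integers(5, 20, size=(n_loci, n_samples))   # enclosing
    read_counts[..., 1] = rng.integers(10, 40, size=(n_loci, n_samples))  # spanning
    read_counts[..., 2] = rng.integers(0, 3, size=(n_loci, n_samples))    # FRR
    read_counts[..., 3] = rng.integers(2, 15, size=(n_loci, n_samples))   # flanking
    missing = np.zeros((n_loci, n_samples), dtype=bool)

    noise = config.noise
    if noise.total > 0:
        total_calls = n_loci * n_samples
        flat = rng.permutation(total_calls)
        pos = 0

        def take(frac: float) -> tuple[np.ndarray, np.ndarray]:
            nonlocal pos
            k = int(round(frac * total_calls))
            sel = flat[pos : pos + k]
            pos += k
            return np.unravel_index(sel, (n_loci, n_samples))

        li, si = take(noise.missing_rate)
        missing[li, si] = True
        truth.noise_injections["missing"] = len(li)
        li, si = take(noise.low_depth_fraction)
        depth[li, si] = rng.integers(5, 50, size=len(li))
        truth.noise_injections["min_depth"] = len(li)
        li, si = take(noise.high_depth_fraction)
        depth[li, si] = rng.integers(1001, 2000, size=len(li))
        truth.noise_injections["max_depth"] = len(li)
        li, si = take(noise.low_quality_fraction)
        quality[li, si] = rng.uniform(0.30, 0.89, size=len(li))
        truth.noise_injections["min_quality"] = len(li)
        li, si = take(noise.bad_ci_fraction)
        ci_lo_bp[li, si, :] = allele_bp[li, si, :] + periods[li, None]
        ci_hi_bp[li, si, :] = allele_bp[li, si, :] + 3 * periods[li, None]
        truth.noise_injections["ml_outside_ci"] = len(li)
        li, si = take(noise.spanbound_only_fraction)
        read_counts[li, si, 0] = 0
        read_counts[li, si, 2] = 0
        truth.noise_injections["spanbound_only"] = len(li)

    # --------------------------------------------------------------------- AIM
    panel = simulate_aim_panel(rng, config.n_aim_markers, config.fst)
    base_q = np.array([GROUP_ADMIXTURE[g] for g in group_of])
    true_q = np.empty((n_samples, 4))
    for j in range(n_samples):
        true_q[j] = rng.dirichlet(base_q[j] * 1200.0)
    dosages = rng.binomial(2, np.clip(true_q @ panel.freqs.T, 1e-9, 1 - 1e-9)).astype(float)
    truth.true_admixture = {sid: [round(float(v), 6) for v in true_q[j]]
                            for j, sid in enumerate(sample_ids)}

    return SimulatedCohort(
        config=config,
        samples=samples,
        loci=loci,
        copies=copies,
        allele_bp=allele_bp.astype(np.int32),
        depth=depth,
        quality=quality,
        ci_lo_bp=ci_lo_bp,
        ci_hi_bp=ci_hi_bp,
        read_counts=read_counts,
        missing=missing,
        aim_positions=panel.positions,
        aim_dosages=dosages,
        panel=panel,
        truth=truth,
    )
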