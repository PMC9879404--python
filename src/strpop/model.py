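"""Core domain types shared across the pipeline.

All allele lengths are stored in base pairs (repeat copies x repeat-unit
length). The GangSTR VCF dialect carries copy numbers; conversion to bp
happens at parse time so that every downstream threshold (pathogenic lengths,
conserved-screen columns) lives in one unit system.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

ANCESTRY_GROUPS = (
    "AFR",
    "EUR",
    "EAS",
    "AdmixedAMR",
    "NonadmixedAMR",
    "PAC",
)
SUPERPOPS = ("AFR", "EUR", "EAS", "AMR")
TOTAL_GROUP = "TOTAL"

ROLES = ("proband", "mother", "father", "sibling")


@dataclass(frozen=True, order=True)
class StrLocus:
    """One STR site on the reference (1-based hg19-style coordinates)."""

    chrom: str
    pos: int
    repeat_unit: str
    ref_len_bp: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.repeat_unit) <= 6:
            raise ValueError(
                f"repeat unit period must be 1-6 bp, got {self.repeat_unit!r}"
            )
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_len_bp <= 0:
            raise ValueError(f"reference length must be positive, got {self.ref_len_bp}")

    @property
    def period(self) -> int:
        return len(self.repeat_unit)

    @property
    def key(self) -> tuple[str, int, str]:
        """Merge key for calls from different VCFs at the same site."""
        return (self.chrom, self.pos, self.repeat_unit)


@dataclass
class StrCall:
    """One sample's diploid genotype at one STR locus.

    ``allele_bp`` and ``ci_bp`` are ``None`` when the genotype is uncalled
    (``missing`` set). Read counts follow the GangSTR RC order:
    enclosing, spanning, fully-repetitive (FRR), flanking.
    """

    sample_id: str
    allele_bp: Optional[tuple[int, int]]
    ci_bp: Optional[tuple[tuple[int, int], tuple[int, int]]]
    depth: int = 0
    quality: float = 0.0
    read_counts: tuple[int, int, int, int] = (0, 0, 0, 0)
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            return
        if self.allele_bp is None:
            raise ValueError("non-missing call requires allele lengths")
        if any(a <= 0 for a in self.allele_bp):
            raise ValueError(f"allele lengths must be positive, got {self.allele_bp}")
        if self.ci_bp is not None and any(lo > hi for lo, hi in self.ci_bp):
            raise ValueError(f"CI low must be <= high, got {self.ci_bp}")
        if not 0.0 <= self.quality <= 1.0:
            raise ValueError(f"quality must be in [0,1], got {self.quality}")

    @property
    def longest_bp(self) -> int:
        if self.allele_bp is None:
            raise ValueError("missing call has no alleles")
        return max(self.allele_bp)

    @property
    def shortest_bp(self) -> int:
        if self.allele_bp is None:
            raise ValueError("missing call has no alleles")
        return min(self.allele_bp)


@dataclass
class Sample:
    sample_id: str
    family_id: str
    role: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    self_reported_ancestry: Optional[str] = None
    maternal_age_years: Optional[float] = None
    paternal_age_years: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")


@dataclass(frozen=True)
class PathogenicLocusRecord:
    """Catalog entry for a known disease-associated repeat expansion."""

    gene: str
    locus: StrLocus
    pathogenic_length_bp: int

    def __post_init__(self) -> None:
        if self.pathogenic_length_bp <= 0:
            raise ValueError(
                f"pathogenic length must be positive, got {self.pathogenic_length_bp}"
            )


@dataclass
class GroupLocusStats:
    """Allele-length summary for one (locus, ancestry group) cell.

    ``sd_bp`` is the population standard deviation (ddof 0); ``cov`` is the
    coefficient of variation sd/mean, the conservation metric.
    """

    locus: StrLocus
    group: str
    n_alleles: int
    mean_bp: float
    sd_bp: float
    cov: float
    se_bp: float
    allele_tally: dict[int, int] = field(default_factory=dict)


@dataclass
class DivergentPosition:
    locus: StrLocus
    group: str
    z: float
    pct_diff: float
    mean_group_bp: float
    mean_eur_bp: float
    divergent: bool


@dataclass
class PathogenicHit:
    sample_id: str
    gene: str
    locus: StrLocus
    allele_bp: int
    total_mean_bp: float
    ratio: float
    divergent: bool
    exceeds_pathogenic: bool
    ancestry: Optional[str] = None


@dataclass
class ConservedHit:
    locus: StrLocus
    sample_id: str
    allele_bp: int
    total_mean_bp: float
    total_sd_bp: float
    cov: float
    z_individual: float
    ratio: float
    outlier_3sd: bool
    flagged: bool


@dataclass
class DeNovoEvent:
    family_id: str
    locus: StrLocus
    type: str  # "expansion" | "contraction"
    proband_allele_bp: int
    parental_extreme_bp: int
    fold: float


@dataclass
class AdmixtureVector:
    """Four-way ancestry proportions (AFR, EUR, EAS, AMR), summing to 1."""

    q: tuple[float, float, float, float]
    n_markers_used: int
    loglik: float
    non_identifiable: bool = False

    def __post_init__(self) -> None:
        if any(c < -1e-12 for c in self.q):
            raise ValueError(f"admixture components must be non-negative: {self.q}")
        if abs(sum(self.q) - 1.0) > 1e-9:
            raise ValueError(f"admixture components must sum to 1: {self.q}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SUPERPOPS, self.q))


@dataclass
class AncestryAssignment:
    primary: str
    secondary: Optional[str] = None
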