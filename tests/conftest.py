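import numpy as np
import pytest

from strpop.model import StrCall, StrLocus
from strpop.simulate import (
    ConservedInjection,
    DivergentInjection,
    PathogenicInjection,
    SimConfig,
    simulate_cohort,
)
from strpop.vcf_io import read_pathogenic_catalog


@pytest.fixture(scope="session")
def catalog():
    return read_pathogenic_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A compact cohort exercising every injection type."""
    cfg = SimConfig(
        seed=11,
        n_loci=60,
        group_sizes={g: 12 for g in ("EUR", "AFR", "EAS", "AdmixedAMR", "NonadmixedAMR", "PAC")},
        n_trios=4,
        divergent=(DivergentInjection("AFR", 4),),
        conserved=ConservedInjection(n_loci=2),
        pathogenic=(PathogenicInjection("TCF4", 2, 51),),
        pathogenic_catalog=tuple(catalog),
        denovo_rate=2e-3,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    paths = small_cohort.write(outdir)
    return paths


def make_call(
    sample_id="S1",
    allele_bp=(30, 36),
    ci_bp="auto",
    depth=60,
    quality=0.99,
    read_counts=(10, 20, 2, 5),
    missing=False,
):
    """StrCall factory with filter-passing defaults."""
    if missing:
        return StrCall(sample_id=sample_id, allele_bp=None, ci_bp=None, missing=True)
    if ci_bp == "auto":
        ci_bp = tuple((a - 3, a + 3) for a in allele_bp)
    return StrCall(
        sample_id=sample_id,
        allele_bp=allele_bp,
        ci_bp=ci_bp,
        depth=depth,
        quality=quality,
        read_counts=read_counts,
    )


def random_calls(rng: np.random.Generator, n: int) -> list[StrCall]:
    """Random calls spanning pass/fail regions of every filter."""
    out = []
    for i in range(n):
        if rng.random() < 0.05:
            out.append(make_call(sample_id=f"S{i}", missing=True))
            continue
        a = tuple(int(v) for v in rng.integers(10, 200, size=2))
        width = int(rng.integers(0, 10))
        off = int(rng.integers(-6, 7))
        ci = tuple((max(1, x + off - width), x + off + width) for x in a)
        rc = tuple(int(v) for v in rng.integers(0, 12, size=4))
        out.append(
            StrCall(
                sample_id=f"S{i}",
                allele_bp=a,
                ci_bp=ci,
                depth=int(rng.integers(0, 1500)),
                quality=float(rng.uniform(0.5, 1.0)),
                read_counts=rc,
            )
        )
    return out


@pytest.fixture
def locus():
    return StrLocus(chrom="1", pos=1000, repeat_unit="CAG", ref_len_bp=30)
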