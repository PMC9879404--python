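"""Readers and writers for the pipeline's on-disk formats.

Covers the GangSTR VCF dialect (repeat copy numbers plus per-allele bootstrap
confidence intervals, depth, quality and read-class counts), 5-column
pedigrees, the pathogenic-locus catalog and generic TSV result files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields, is_dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

from .model import PathogenicLocusRecord, Sample, StrCall, StrLocus, ROLES

log = logging.getLogger(__name__)


class StrVcfParseError(ValueError):
    """Malformed VCF content (carries the offending position when known)."""


class StrVcfDialectError(ValueError):
    """The VCF header lacks the FORMAT/INFO keys the dialect requires."""


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class VcfDialect:
    """Key names of the GangSTR-style fields, overridable for variants.

    ``allele_unit`` says what REPCN-style genotypes are expressed in:
    ``"copies"`` (GangSTR default; converted to bp as copies x period at parse
    time) or ``"bp"`` (already base pairs, stored as-is).
    """

    repeat_unit_key: str = "RU"
    genotype_key: str = "REPCN"
    ci_key: str = "REPCI"
    depth_key: str = "DP"
    quality_key: str = "Q"
    read_counts_key: str = "RC"
    allele_unit: str = "copies"


GANGSTR_DIALECT = VcfDialect()


def _parse_ci(raw: str, period: int, to_bp: bool) -> tuple[tuple[int, int], tuple[int, int]]:
    parts = raw.split(",")
    if len(parts) != 2:
        raise StrVcfParseError(f"expected two comma-separated CIs, got {raw!r}")
    out = []
    for part in parts:
        lo_s, _, hi_s = part.partition("-")
        lo, hi = int(lo_s), int(hi_s)
        if to_bp:
            lo, hi = lo * period, hi * period
        out.append((lo, hi))
    return out[0], out[1]


def read_str_vcf(
    path: str | Path,
    dialect: VcfDialect = GANGSTR_DIALECT,
) -> Iterator[tuple[StrLocus, list[StrCall]]]:
    """Stream (locus, calls) pairs from a GangSTR-dialect VCF in file order.

    Copy numbers are converted to base pairs with exact integer arithmetic.
    Missing genotypes yield ``StrCall(missing=True)``. Records whose repeat
    unit falls outside the 1-6 bp STR definition are skipped with a warning.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise StrVcfParseError(f"{path}: cannot parse VCF: {exc}") from exc
    with vcf:
        fmts = set(vcf.header.formats.keys())
        required = {dialect.genotype_key, dialect.depth_key}
        if not required <= fmts:
            raise StrVcfDialectError(
                f"{path}: FORMAT lacks {sorted(required - fmts)}; not the expected dialect"
            )
        if dialect.repeat_unit_key not in vcf.header.info:
            raise StrVcfDialectError(
                f"{path}: INFO lacks {dialect.repeat_unit_key}; not the expected dialect"
            )
        for rec in vcf:
            unit = rec.info.get(dialect.repeat_unit_key)
            if isinstance(unit, tuple):
                unit = unit[0]
            if unit is None:
                raise StrVcfParseError(
                    f"{path}:{rec.chrom}:{rec.pos}: record lacks repeat unit"
                )
            unit = str(unit).upper()
            if not 1 <= len(unit) <= 6:
                log.warning(
                    "%s:%s:%d: repeat unit %r outside 1-6 bp, locus skipped",
                    path, rec.chrom, rec.pos, unit,
                )
                continue
            period = len(unit)
            locus = StrLocus(
                chrom=rec.chrom,
                pos=rec.pos,
                repeat_unit=unit,
                ref_len_bp=len(rec.ref) if rec.ref else period,
            )
            to_bp = dialect.allele_unit == "copies"
            calls = []
            for name, smp in rec.samples.items():
                calls.append(_parse_sample(path, rec, name, smp, dialect, period, to_bp))
            yield locus, calls


def _parse_sample(path, rec, name, smp, dialect, period, to_bp) -> StrCall:
    gt = smp.get("GT")
    raw = smp.get(dialect.genotype_key)
    uncalled = (
        raw is None
        or (isinstance(raw, tuple) and any(v is None for v in raw))
        or gt is None
        or any(a is None for a in gt)
    )
    if uncalled:
        return StrCall(sample_id=name, allele_bp=None, ci_bp=None, missing=True)
    if isinstance(raw, str):
        vals = tuple(int(v) for v in raw.split(","))
    elif isinstance(raw, tuple):
        vals = tuple(int(v) for v in raw)
    else:
        vals = (int(raw),)
    if len(vals) != 2:
        raise StrVcfParseError(
            f"{path}:{rec.chrom}:{rec.pos}: sample {name}: expected 2 copy numbers, got {vals}"
        )
    mult = period if to_bp else 1
    allele_bp = (vals[0] * mult, vals[1] * mult)
    ci_raw = smp.get(dialect.ci_key)
    ci_bp = None
    if ci_raw is not None:
        if isinstance(ci_raw, tuple):
            ci_raw = ",".join(str(v) for v in ci_raw)
        try:
            ci_bp = _parse_ci(str(ci_raw), period, to_bp)
        except (ValueError, StrVcfParseError) as exc:
            raise StrVcfParseError(
                f"{path}:{rec.chrom}:{rec.pos}: sample {name}: bad CI {ci_raw!r}"
            ) from exc
    rc_raw = smp.get(dialect.read_counts_key)
    if rc_raw is None:
        rc = (0, 0, 0, 0)
    else:
        if isinstance(rc_raw, tuple):
            rc_vals = [int(v) for v in rc_raw]
        else:
            rc_vals = [int(v) for v in str(rc_raw).split(",")]
        if len(rc_vals) != 4:
            raise StrVcfParseError(
                f"{path}:{rec.chrom}:{rec.pos}: sample {name}: expected 4 read-class counts"
            )
        rc = tuple(rc_vals)
    q = smp.get(dialect.quality_key)
    dp = smp.get(dialect.depth_key)
    return StrCall(
        sample_id=name,
        allele_bp=allele_bp,
        ci_bp=ci_bp,
        depth=int(dp) if dp is not None else 0,
        quality=float(q) if q is not None else 0.0,
        read_counts=rc,
        missing=False,
    )


def read_str_vcfs(
    paths: Sequence[str | Path],
    dialect: VcfDialect = GANGSTR_DIALECT,
) -> dict[tuple[str, int, str], tuple[StrLocus, list[StrCall]]]:
    """Merge several (typically single-sample) VCFs by locus key.

    A locus present in one file but absent from another simply has no call
    for the absent samples; downstream code treats that as missing.
    """
    merged: dict[tuple[str, int, str], tuple[StrLocus, list[StrCall]]] = {}
    for path in paths:
        for locus, calls in read_str_vcf(path, dialect=dialect):
            if locus.key in merged:
                merged[locus.key][1].extend(calls)
            else:
                merged[locus.key] = (locus, list(calls))
    return merged


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit">',
    '##INFO=<ID=PERIOD,Number=1,Type=Integer,Description="Repeat unit length in bp">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=Q,Number=1,Type=Float,Description="Genotype quality in [0,1]">',
    '##FORMAT=<ID=REPCN,Number=1,Type=String,Description="Genotype in repeat-unit copies">',
    '##FORMAT=<ID=REPCI,Number=1,Type=String,Description="95% bootstrap CI per allele, in copies">',
    '##FORMAT=<ID=RC,Number=1,Type=String,Description="Read counts: enclosing,spanning,FRR,flanking">',
]


def write_str_vcf(
    path: str | Path,
    records: Iterable[tuple[StrLocus, list[StrCall]]],
    sample_ids: Sequence[str],
) -> None:
    """Write a multi-sample GangSTR-dialect VCF as deterministic plain text.

    Allele lengths are emitted back as copy numbers (bp / period; the pipeline
    only ever stores bp that came from whole copy numbers, so the division is
    exact).
    """
    path = Path(path)
    records = list(records)
    contigs: list[str] = []
    for locus, _ in records:
        if locus.chrom not in contigs:
            contigs.append(locus.chrom)
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for locus, calls in records:
            period = locus.period
            ref = (locus.repeat_unit * ((locus.ref_len_bp + period - 1) // period))[
                : locus.ref_len_bp
            ]
            cols = [
                locus.chrom,
                str(locus.pos),
                ".",
                ref,
                ".",
                ".",
                "PASS",
                f"RU={locus.repeat_unit};PERIOD={period}",
                "GT:DP:Q:REPCN:REPCI:RC",
            ]
            by_sample = {}
            for c in calls:
                by_sample[c.sample_id] = c
            for sid in sample_ids:
                c = by_sample.get(sid)
                if c is None or c.missing:
                    cols.append("./.:.:.:.:.:.")
                    continue
                cn = tuple(a // period for a in c.allele_bp)
                if c.ci_bp is not None:
                    ci = ",".join(f"{lo // period}-{hi // period}" for lo, hi in c.ci_bp)
                else:
                    ci = ",".join(f"{v}-{v}" for v in cn)
                rc = ",".join(str(v) for v in c.read_counts)
                cols.append(f"0/0:{c.depth}:{c.quality:g}:{cn[0]},{cn[1]}:{ci}:{rc}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    samples: list[Sample]

    def __post_init__(self) -> None:
        self.by_id = {s.sample_id: s for s in self.samples}

    def trios(self) -> list[tuple[Sample, Sample, Sample]]:
        """Complete trios (proband, mother, father) sharing a family id."""
        by_family: dict[str, dict[str, Sample]] = {}
        for s in self.samples:
            by_family.setdefault(s.family_id, {})[s.role + ":" + s.sample_id] = s
        out = []
        for fam in sorted(by_family):
            members = by_family[fam].values()
            probands = [s for s in members if s.role == "proband"]
            mothers = [s for s in members if s.role == "mother"]
            fathers = [s for s in members if s.role == "father"]
            if probands and mothers and fathers:
                for p in sorted(probands, key=lambda s: s.sample_id):
                    out.append((p, mothers[0], fathers[0]))
        return out

    def singleton_probands(self) -> list[Sample]:
        """Probands with neither parent in the data set."""
        out = []
        for s in self.samples:
            if s.role != "proband":
                continue
            parents_present = any(
                o.family_id == s.family_id and o.role in ("mother", "father")
                for o in self.samples
            )
            if not parents_present:
                out.append(s)
        return out


_MISSING_PARENT = {"0", ".", "", "NA"}


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a tab-separated pedigree.

    Required columns: family, sample, father, mother, role ("0" = absent
    parent). Optional columns: self_reported_ancestry, maternal_age,
    paternal_age.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["family", "sample", "father", "mother", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeError(f"{path}: pedigree lacks columns {missing}")
    if df["sample"].duplicated().any():
        dups = sorted(df.loc[df["sample"].duplicated(), "sample"])
        raise PedigreeError(f"{path}: duplicate sample ids {dups}")
    samples = []
    for row in df.itertuples(index=False):
        if row.role not in ROLES:
            raise PedigreeError(f"{path}: unknown role {row.role!r} for {row.sample}")
        if row.sample in (row.father, row.mother):
            raise PedigreeError(f"{path}: sample {row.sample} listed as its own parent")
        sra = getattr(row, "self_reported_ancestry", "") or None
        mat = getattr(row, "maternal_age", "")
        pat = getattr(row, "paternal_age", "")
        samples.append(
            Sample(
                sample_id=row.sample,
                family_id=row.family,
                role=row.role,
                father_id=None if row.father in _MISSING_PARENT else row.father,
                mother_id=None if row.mother in _MISSING_PARENT else row.mother,
                self_reported_ancestry=sra,
                maternal_age_years=float(mat) if mat not in ("", ".") else None,
                paternal_age_years=float(pat) if pat not in ("", ".") else None,
            )
        )
    return Pedigree(samples)


def write_pedigree(path: str | Path, samples: Sequence[Sample]) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "family": s.family_id,
                "sample": s.sample_id,
                "father": s.father_id or "0",
                "mother": s.mother_id or "0",
                "role": s.role,
                "self_reported_ancestry": s.self_reported_ancestry or "",
                "maternal_age": "" if s.maternal_age_years is None else f"{s.maternal_age_years:g}",
                "paternal_age": "" if s.paternal_age_years is None else f"{s.paternal_age_years:g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pathogenic catalog


def packaged_catalog_path() -> Path:
    return Path(resources.files("strpop").joinpath("data/pathogenic_catalog.tsv"))


def read_pathogenic_catalog(path: str | Path | None = None) -> list[PathogenicLocusRecord]:
    """Read the pathogenic-locus catalog (gene, chrom, pos, unit, length).

    With no path, the packaged catalog of six well-characterised expansion
    loci is used.
    """
    if path is None:
        path = packaged_catalog_path()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        log.warning("%s: empty pathogenic catalog", path)
        return []
    records = []
    for row in df.itertuples(index=False):
        length = int(row.pathogenic_length_bp)
        records.append(
            PathogenicLocusRecord(
                gene=row.gene,
                locus=StrLocus(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    repeat_unit=row.repeat_unit,
                    ref_len_bp=int(getattr(row, "ref_len_bp", 0) or len(row.repeat_unit)),
                ),
                pathogenic_length_bp=length,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Generic results TSV


def _flatten(rec) -> dict:
    if is_dataclass(rec):
        d = {}
        for f in dc_fields(rec):
            v = getattr(rec, f.name)
            if isinstance(v, StrLocus):
                d["chrom"] = v.chrom
                d["pos"] = v.pos
                d["repeat_unit"] = v.repeat_unit
                d["ref_len_bp"] = v.ref_len_bp
            elif isinstance(v, dict):
                d[f.name] = ";".join(f"{k}:{v[k]}" for k in sorted(v))
            elif isinstance(v, tuple):
                d[f.name] = ",".join(str(x) for x in v)
            else:
                d[f.name] = v
        return d
    if isinstance(rec, dict):
        return dict(rec)
    raise TypeError(f"cannot serialize record of type {type(rec)}")


def write_results_tsv(records: Sequence, path: str | Path, columns: Optional[list[str]] = None) -> None:
    """Write screen-output records to TSV with a deterministic row order.

    Rows are sorted by (chrom, pos, sample) over whichever of those columns
    exist; an empty record list yields a header-only file when ``columns`` is
    given, else an empty file with a comment header.
    """
    rows = [_flatten(r) for r in records]
    if not rows:
        with open(path, "w") as fh:
            fh.write("\t".join(columns or []) + "\n")
        return
    df = pd.DataFrame(rows)
    sort_cols = [c for c in ("chrom", "pos", "sample_id", "family_id", "group", "gene") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    if columns:
        df = df[columns]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
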