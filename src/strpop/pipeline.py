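"""End-to-end orchestration: filter -> ancestry -> cohort split -> baseline ->
four screens, with a deterministic run manifest.

The cohort split mirrors the three partially overlapping study groups:
population cohort (all parents plus probands with no sequenced parent, the
baseline source), proband cohort (all probands, screened for expansions) and
trio cohort (complete trios, screened for de novo mutations). Siblings are
parsed but excluded from every cohort.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import conserved as conserved_mod
from . import denovo as denovo_mod
from . import divergence as divergence_mod
from . import pathogenic as pathogenic_mod
from .ancestry import AimPanel, assign_ancestry, estimate_admixture, read_aim_genotypes
from .filters import FilterParams, filter_cohort
from .model import ANCESTRY_GROUPS, Sample, StrLocus
from .popstats import build_population_baseline, population_cohort_ids, save_baseline
from .vcf_io import (
    Pedigree,
    read_pathogenic_catalog,
    read_pedigree,
    read_str_vcfs,
    write_results_tsv,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class ScreenThresholds:
    z_threshold: float = 5.0
    pct_threshold: float = 0.20
    divergence_min_n: int = 10
    top_k: int = 20
    pathogenic_ratio: float = 1.5
    cov_threshold: float = 0.075
    sd_mult: float = 3.0
    ratio_min: float = 2.5
    expansion_factor: float = 2.0
    contraction_factor: float = 0.5


@dataclass
class PipelineConfig:
    vcfs: Sequence[str | Path]
    pedigree: str | Path
    panel: str | Path
    aim_genotypes: str | Path
    out_dir: str | Path
    catalog: Optional[str | Path] = None  # default: packaged six-gene catalog
    filter_params: FilterParams = field(default_factory=FilterParams)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    allele_mode: str = "pooled"
    seed: int = 0


def split_cohorts(
    pedigree: Pedigree,
) -> tuple[list[str], list[str], list[tuple[Sample, Sample, Sample]]]:
    """(population cohort ids, proband cohort ids, complete trios)."""
    population = population_cohort_ids(pedigree.samples)
    probands = sorted(s.sample_id for s in pedigree.samples if s.role == "proband")
    return population, probands, pedigree.trios()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def assign_cohort_ancestry(
    pedigree: Pedigree,
    panel: AimPanel,
    aim_samples: Sequence[str],
    aim_dosages: np.ndarray,
) -> dict[str, str]:
    """Primary-ancestry label per sample from AIM dosages + self-report."""
    idx = {s: i for i, s in enumerate(aim_samples)}
    assignment = {}
    for s in pedigree.samples:
        if s.sample_id not in idx:
            raise PipelineError("ancestry", f"sample {s.sample_id} has no AIM genotypes")
        q = estimate_admixture(aim_dosages[idx[s.sample_id]], panel)
        assignment[s.sample_id] = assign_ancestry(q, s.self_reported_ancestry).primary
    return assignment


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write result TSVs and a manifest; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "filter_params": asdict(config.filter_params),
        "inputs": {},
        "stages": [],
        "outputs": {},
        "complete": False,
    }
    t = config.thresholds

    def stage_done(name: str, **counts) -> None:
        manifest["stages"].append({"name": name, **counts})

    try:
        # 1. load ------------------------------------------------------------
        vcf_paths = [Path(p) for p in config.vcfs]
        for p in [*vcf_paths, Path(config.pedigree), Path(config.panel), Path(config.aim_genotypes)]:
            manifest["inputs"][str(p)] = _sha256(p)
        merged = read_str_vcfs(vcf_paths)
        calls_by_locus = {locus: calls for locus, calls in merged.values()}
        pedigree = read_pedigree(config.pedigree)
        panel = AimPanel.from_tsv(config.panel)
        aim_samples, _positions, aim_dosages = read_aim_genotypes(config.aim_genotypes)
        catalog = read_pathogenic_catalog(config.catalog)
        stage_done("load", n_loci=len(calls_by_locus), n_samples=len(pedigree.samples))

        # 2. filter ----------------------------------------------------------
        kept, summary = filter_cohort(calls_by_locus, config.filter_params)
        stage_done(
            "filter",
            n_input=summary.n_input,
            n_kept=summary.n_kept,
            n_dropped=summary.n_dropped,
            dropped_by_reason=dict(sorted(summary.dropped_by_reason.items())),
        )

        # 3. ancestry ----------------------------------------------------------
        assignment = assign_cohort_ancestry(pedigree, panel, aim_samples, aim_dosages)
        counts = pd.Series(list(assignment.values())).value_counts().to_dict()
        ancestry_df = pd.DataFrame(
            sorted(assignment.items()), columns=["sample", "primary"]
        )
        ancestry_path = out / "ancestry.tsv"
        ancestry_df.to_csv(ancestry_path, sep="\t", index=False)
        stage_done("ancestry", per_group={k: int(v) for k, v in sorted(counts.items())})

        # 4. cohorts -----------------------------------------------------------
        population_ids, proband_ids, trios = split_cohorts(pedigree)
        stage_done(
            "cohorts",
            n_population=len(population_ids),
            n_probands=len(proband_ids),
            n_trios=len(trios),
        )
        if not any(assignment[s] == "EUR" for s in population_ids):
            raise PipelineError("divergence", "no European samples in the population cohort; "
                                "the divergence screen has no comparison group")

        # 5. baseline ----------------------------------------------------------
        pop_samples = [s for s in pedigree.samples]
        baseline = build_population_baseline(kept, pop_samples, assignment, mode=config.allele_mode)
        baseline_path = out / "baseline.tsv"
        save_baseline(baseline, baseline_path)
        stage_done("baseline", n_rows=len(baseline))

        # 6. divergence --------------------------------------------------------
        groups_present = [
            g for g in ANCESTRY_GROUPS
            if g != "EUR" and (baseline[(baseline["group"] == g) & (baseline["n"] > 0)]).shape[0] > 0
        ]
        all_divergent = {}
        div_counts = {}
        for g in groups_present:
            records, scatter = divergence_mod.screen_all_loci(
                baseline, g, t.z_threshold, t.pct_threshold, t.divergence_min_n
            )
            all_divergent[g] = records
            div_counts[g] = len(records)
            scatter.to_csv(out / f"scatter_{g}.tsv", sep="\t", index=False, float_format="%.10g")
            write_results_tsv(records, out / f"divergent_{g}.tsv")
            write_results_tsv(
                divergence_mod.top_divergent(records, t.top_k), out / f"top_divergent_{g}.tsv"
            )
        shared = divergence_mod.shared_loci(all_divergent) if len(all_divergent) >= 2 else {}
        with open(out / "shared_loci.tsv", "w") as fh:
            fh.write("chrom\tpos\trepeat_unit\tgroups\n")
            for key in sorted(shared):
                fh.write(f"{key[0]}\t{key[1]}\t{key[2]}\t{','.join(sorted(shared[key]))}\n")
        stage_done("divergence", divergent_per_group=div_counts, n_shared=len(shared))

        # 7. pathogenic --------------------------------------------------------
        proband_set = set(proband_ids)
        proband_calls = {
            locus: [c for c in calls if c.sample_id in proband_set]
            for locus, calls in kept.items()
        }
        hits = pathogenic_mod.screen_pathogenic(
            proband_calls, catalog, baseline, t.pathogenic_ratio, assignment
        )
        write_results_tsv([h for h in hits if h.divergent or h.exceeds_pathogenic],
                          out / "pathogenic_hits.tsv")
        pathogenic_mod.summarize_by_gene(hits).to_csv(
            out / "pathogenic_by_gene.tsv", sep="\t", index=False
        )
        pathogenic_mod.ancestral_mean_at_pathogenic_loci(baseline, catalog).to_csv(
            out / "pathogenic_ancestral_means.tsv", sep="\t", index=False, float_format="%.10g"
        )
        stage_done(
            "pathogenic",
            n_divergent=sum(h.divergent for h in hits),
            n_exceeds=sum(h.exceeds_pathogenic for h in hits),
        )

        # 8. conserved ---------------------------------------------------------
        cons_hits = conserved_mod.screen_conserved_outliers(
            proband_calls, baseline, t.cov_threshold, t.sd_mult, t.ratio_min
        )
        write_results_tsv(cons_hits, out / "conserved_outliers_3sd.tsv")
        write_results_tsv([h for h in cons_hits if h.flagged], out / "conserved_flagged.tsv")
        stage_done(
            "conserved",
            n_3sd=len(cons_hits),
            n_flagged=sum(h.flagged for h in cons_hits),
        )

        # 9. denovo ------------------------------------------------------------
        scan = denovo_mod.scan_trios(kept, trios, t.expansion_factor, t.contraction_factor)
        write_results_tsv(scan.events, out / "denovo_events.tsv")
        per_proband = pd.DataFrame(
            {
                "sample": list(scan.expansions_per_proband),
                "n_expansions": list(scan.expansions_per_proband.values()),
                "n_contractions": [scan.contractions_per_proband[s] for s in scan.expansions_per_proband],
                "n_loci_screened": [scan.n_loci_screened[s] for s in scan.expansions_per_proband],
            }
        ).sort_values("sample")
        per_proband.to_csv(out / "denovo_per_proband.tsv", sep="\t", index=False)
        ages = denovo_mod.parental_age_summary(scan.expansions_per_proband, pedigree.samples)
        stage_done(
            "denovo",
            n_expansions=sum(1 for e in scan.events if e.type == "expansion"),
            n_contractions=sum(1 for e in scan.events if e.type == "contraction"),
            parental_age=ages,
        )
    except PipelineError:
        manifest["complete"] = False
        _write_manifest(manifest, out)
        raise
    except Exception as exc:  # annotate with the failing stage
        stage_names = ["load", "filter", "ancestry", "cohorts", "baseline",
                       "divergence", "pathogenic", "conserved", "denovo"]
        current = stage_names[min(len(manifest["stages"]), len(stage_names) - 1)]
        manifest["complete"] = False
        _write_manifest(manifest, out)
        raise PipelineError(current, str(exc)) from exc

    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    manifest["complete"] = True
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# Interval annotation (exon/intron labels for screen hits)


class IntervalFileError(ValueError):
    pass


def annotate_intervals(
    hits: Sequence, interval_path: str | Path, unannotated: str = "N/A"
) -> list[str]:
    """Label each hit with the overlapping feature(s) from a BED-style file.

    The file is 0-based half-open on disk (chrom, start, end, label) and must
    be sorted by (chrom, start); internally positions are 1-based, so a hit at
    1-based position p overlaps [start+1, end] — the interval start is
    included. Hits overlapping nothing are labeled ``unannotated``.
    """
    df = pd.read_csv(
        interval_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label"],
        dtype={"chrom": str, "start": int, "end": int, "label": str},
    )
    for chrom, sub in df.groupby("chrom"):
        if not sub["start"].is_monotonic_increasing:
            raise IntervalFileError(
                f"intervals on {chrom} are not sorted by start; sort the file first"
            )
    labels = []
    for h in hits:
        locus: StrLocus = h.locus if hasattr(h, "locus") else h
        sub = df[df["chrom"] == locus.chrom]
        over = sub[(sub["start"] + 1 <= locus.pos) & (locus.pos <= sub["end"])]
        labels.append(";".join(over["label"]) if len(over) else unannotated)
    return labels
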