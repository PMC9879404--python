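# Methods

This note documents the statistical procedures `strpop` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions used at
edge cases.

## Units and data model

Allele lengths are stored in **base pairs** throughout: STR genotypers report
repeat copy numbers, which are converted at parse time as
`length_bp = copies × period` (exact integer arithmetic; the period is the
repeat-unit length, 1–6 bp). Everything downstream — pathogenic cutoffs,
conserved-screen columns, de novo folds — is expressed in bp, so one unit
system covers all screens. Positions are 1-based as in VCF; loci are keyed by
`(chrom, pos, repeat_unit)` when merging calls across files, and a locus
absent from one sample's VCF is a missing call for that sample, not an error.

## Call-level filters

Calls are kept only if all enabled predicates pass; all failed reasons are
reported, not just the first:

| parameter | default | meaning |
| --- | --- | --- |
| `min_depth` | 50 | minimum read depth (kept at exactly 50) |
| `max_depth` | 1000 | maximum depth, against collapsed repeats/CNVs |
| `min_quality` | 0.90 | genotyper quality score in [0,1], inclusive |
| `require_supported_reads` | on | drop calls whose evidence cannot bound the allele |
| `require_ml_in_ci` | on | each allele must lie inside its own 95% bootstrap CI |

Threshold inequalities are inclusive on the keep side; the sources that
publish these cutoffs print them without strictness, and inclusive reading
keeps a call *at* the stated threshold.

"Unsupported" evidence is defined via read classes: of the four GangSTR read
classes (enclosing, spanning, fully-repetitive, flanking), only enclosing and
fully-repetitive reads bound the allele length. A call whose enclosing and
fully-repetitive counts are both zero is dropped (`spanbound_only`; or
`no_supporting_reads` when all four classes are zero). The class mask is
configurable.

Filtering is per call and per locus: an individual failing filters at one
locus is excluded from statistics at that locus only. The predicates are
idempotent and monotone in their thresholds (property-tested).

## Population statistics

For every locus and every ancestry group (plus the pooled TOTAL), the package
computes the allele tally, mean, **population** standard deviation (ddof 0),
coefficient of variation `CV = σ/μ`, and standard error `σ/√n`. Both alleles
of each individual contribute by default (`pooled`); a longest-allele-only
mode exists because allele-level versus individual-level tallying is a
genuine modelling choice. Individuals with a secondary ancestry contribute
only to their primary group.

The *population cohort* that feeds these baselines contains all parents plus
probands with **no** sequenced parent; a proband with even one sequenced
parent is excluded (the parent already represents the family). Siblings are
parsed but excluded from all cohorts.

A single-pass accumulator (tally + Σx + Σx²) backs the per-locus API; a
vectorized numpy path produces whole-cohort baselines. The two are tested to
agree exactly on tallies and to 1e-9 relative on moments.

## Ancestry from AIMs

Supervised admixture under the binomial mixture model: for dosage `g_i` at
marker `i`, `log L(q) = Σ_i [g_i log p_i + (2−g_i) log(1−p_i)]` with
`p_i = Σ_k q_k f_ki`. The maximiser over the 3-simplex is found by EM with a
fixed uniform start — deterministic for fixed input, log-likelihood
non-decreasing per iteration (both tested; EM solutions match a 0.01-grid
search over the simplex on small instances). Panel frequencies are clamped to
[1e-3, 1−1e-3] so fixed alleles cannot produce infinite log-likelihoods. A
panel whose four frequency columns are identical makes `q` unidentifiable;
the estimator returns the uniform vector and sets a flag rather than
pretending to know.

Assignment rules, in order: Pacific-Islander self-report → `PAC` (no PAC
reference population exists in the 4-way panel; these individuals present as
European/East-Asian blends); `q_AMR > 0.75` → `NonadmixedAMR`; any component
`> 0.60` → primary (AMR → `AdmixedAMR`); a maximum in `[0.50, 0.60]` →
primary plus the runner-up as secondary; otherwise `unassigned`. Argmax ties
break by the fixed population order (AFR, EUR, EAS, AMR).

Reference panels are curated by iterating {estimate frequencies from current
members → estimate each member's admixture → evict members whose own-label
component falls below a threshold} to a fixed point, then downsampling each
population to at most 300 members with a seeded RNG. The eviction threshold
default is 0.75 own-fraction; it is a configurable judgment call (no
published value exists for it) and is logged.

## The four screens

**Ancestry divergence.** `z = (μ_g − μ_EUR)/σ_EUR`,
`pct = |μ_g − μ_EUR|/μ_EUR`; divergent iff `|z| > 5` and `pct > 0.20`, both
strict. The European SD is the denominator by definition of the screen (how
many European SDs away the group mean sits); a two-sample z using combined
standard errors is available behind `z_mode="two_sample"`. Both groups need
at least `min_n = 10` alleles (tiny groups otherwise produce unstable means);
`σ_EUR = 0` with unequal means yields `z = ±∞` and the percent criterion
decides; `μ_EUR = 0` skips the locus. No multiple-testing correction is
applied — the screen is a fixed-threshold filter, not a hypothesis test, and
corrections would change its meaning. Top-k ranking is by `|z|` descending
with ties broken by percent difference and then locus key, so output order is
deterministic.

**Pathogenic loci.** The longest proband allele at each catalog locus is
compared with the TOTAL baseline mean: *divergent* iff
`allele ≥ ratio × mean` with `ratio = 1.5` by default, and *exceeds
pathogenic* iff `allele > pathogenic_length_bp` (strict). The two flags are
deliberately independent — an allele can exceed a short pathogenic cutoff
without reaching 1.5× a long mean, and vice versa. The published sources for
this screen state both a 150% and a 250% criterion in different places; 1.5×
is the default because it is the value consistent with the printed per-gene
counts, and 2.5× is one configuration switch away. The packaged catalog
carries the six loci with published per-gene outcomes (AR 114 bp, TCF4
150 bp, DMPK 150 bp, DIP2B 600 bp, ATXN10 4000 bp, RFC1 4000 bp); its schema
(gene, chrom, pos, repeat_unit, ref_len_bp, pathogenic_length_bp) is a plain
TSV users can extend.

**Conserved regions.** A locus is conserved iff its TOTAL `CV ≤ 0.075`
(inclusive) with at least `min_n` alleles. "CV" is the interpretation of the
screen's published "covariance": the printed values (0.035–0.070) are
dimensionless and match σ/μ at the printed means, whereas a variance would
carry bp². At conserved loci, probands are flagged in two stages, both
reported: stage 1 when the longest allele is `> μ + 3σ`, stage 2 when it is
additionally `≥ 2.5×μ`. The 2.5 criterion is a **ratio**, not a relative
difference: evaluating the five published worked-example rows, all pass under
the ratio reading (ratios 2.75–3.37) and all fail under
`(allele−μ)/μ ≥ 2.5` (excesses 1.75–2.37), so the ratio reading is the one
that reproduces the published table; the difference reading remains available
as `ratio_mode="excess"`. With `σ = 0` the z-stage is undefined and any
exceedance passes it; the ratio stage then decides alone (logged).

**De novo.** Expansion iff `max(proband) > 2 × max(mother ∪ father)`;
contraction iff `min(proband) < 0.5 × min(mother ∪ father)`; both strict,
both can co-occur at one locus. All three trio members must pass call filters
at the locus — unfiltered parental calls would inflate candidate counts.
The >2× rule is deliberately insensitive to single-repeat stepwise mutations;
the simulator includes a stepwise mode precisely to verify that such events
are never flagged. Per-proband counts and Pearson correlations with parental
ages are reported; fewer than 3 aged probands or zero variance in either
variable is reported as undefined rather than as a number.

## Synthetic cohorts

The generator produces what the pipeline consumes — a multi-sample
GangSTR-dialect VCF, a pedigree, AIM dosages, a reference panel — plus a
ground-truth JSON of every injection. Design:

- **Allele lengths** are discretized normals over repeat copies (rounded,
  floor 1 copy), parameterised per locus by a mean in 8–30 copies and a CV in
  0.05–0.15. This is a deliberate simplification of stepwise mutation
  dynamics: the screens consume only per-locus means, SDs and tails, which
  discretized normals reproduce, and they are far easier to parameterise.
- **Divergent injections** shift one group's mean by `max(shift_sd·σ,
  pct_shift·μ)` (defaults 8 σ and 30%), comfortably beyond the 5 σ / 20%
  screen thresholds at the default 200 alleles per group.
- **Conserved injections** target a CV of 0.03, subtracting the 1/12 variance
  that integer rounding adds. Expansion carriers receive one `⌈3×μ⌉` allele.
  Carriers are drawn from **trio probands** where possible: trio probands are
  outside the population baseline, so at desk-scale cohort sizes the injected
  allele cannot inflate the locus CV past the conservation cutoff — an
  artifact a ~4,000-allele baseline would not have, since one 3× allele moves
  its CV by a negligible amount. When such a carrier clears the >2× parental
  rule it is also recorded as a de novo truth event, keeping the truth table
  complete.
- **Trios** inherit one allele from each parent (Mendelian); de novo jumps
  are applied at a configured rate, expansions as `⌈2.5 × max parental⌉`
  (always detectable by the >2× rule) and contractions as `⌊0.4 × min
  parental⌋` (always below 0.5×), so truth recovery is exact by construction.
  A stepwise mode applies ±1-copy changes instead.
- **AIM genotypes** are Binomial(2, q·f) draws from Balding–Nichols
  population frequencies (ancestral `p ~ U(0.1, 0.9)`, per-population Beta
  divergence). The divergence parameter defaults to `F = 0.5`: AIM panels are
  *selected* for extreme between-population differentiation, so the synthetic
  panel must be far more informative than random SNPs; at 250 markers this
  yields a mean absolute admixture error of ≈ 0.04 for fully admixed
  individuals. Group compositions put each group's defining component well
  clear of the 0.60/0.75 assignment boundaries, with Dirichlet jitter tight
  enough (concentration 1200) that misassignment is rare.
- **Genotyping noise is off by default** (constant high quality, tight CIs,
  supported read classes), so truth-recovery tests are exact. An optional
  noise model injects disjoint sets of missing, low/high-depth, low-quality,
  CI-excluding and spanbound-only calls at configured fractions, with the
  injected counts recorded in the truth table for filter accounting.

Everything derives from one integer seed; two runs with the same seed are
byte-identical, which the pipeline's manifest (SHA-256 digests of inputs and
outputs) makes checkable end to end.

What the generator does **not** emulate: read-level errors and stutter
(lengths are drawn, not called from reads), genotyper bias at long alleles
(real short-read callers saturate above ~150 bp), linkage between loci,
X-hemizygosity (all samples are diploid everywhere), and realistic
population-size imbalance. Passing tests therefore demonstrate the screens'
correctness given called genotypes with the assumed distributional structure,
not robustness to caller artifacts on real data.

## Problem sizes

The shipped tests and the acceptance script evaluate: the divergence screen
on 6 groups × 5,000 loci × 200 alleles per group with 50 injected loci; the
de novo screen on 100 trios × 1,000 loci at rate 1e-3; admixture on 100
individuals × 250 markers (with grid-search cross-checks at 50 markers);
statistics oracles on 1,000 random loci; and full pipeline runs on ~500-locus
six-group cohorts. These sizes keep a full run in the tens of seconds while
leaving per-group sampling error an order of magnitude below every screen
threshold.

## Known limitations

- The conserved screen's two stages can disagree with published aggregate
  counts whose definitions cannot be reconciled from their source; both stage
  outputs are emitted separately rather than forcing a match.
- Hemizygous male X loci are treated like autosomal diploid calls; the
  genotypes-present convention decides how many alleles an individual
  contributes.
- The pathogenic catalog ships only the six loci with published outcomes;
  extending it is a one-line-per-locus TSV edit.
- `unassigned` individuals (no admixture component ≥ 0.50) contribute to
  TOTAL baselines but to no group, matching the assignment rules' silence
  about them.
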