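# Methods

## The assay being modelled

A tumor-informed MRD assay profiles each patient's tumor (FFPE tissue
against matched white blood cells, a 95-gene panel), selects a small
personalized set of somatic mutations, and re-measures exactly those
loci in serial plasma samples by multiplex amplicon sequencing at
~100,000X. Because the tracked mutations are known a priori, plasma
analysis reduces to counting alt-supporting reads at a handful of
sites and comparing each variant allele fraction (VAF) to a detection
limit calibrated against background sequencing error. `mrdtrack`
implements everything downstream of alignment and raw variant
calling: variant-table ingestion, cohort summaries, actionability
annotation, panel selection, LOD calibration, positivity calling and
longitudinal interpretation. Wet-lab steps, read alignment, somatic
calling, CHIP removal and VEP annotation are upstream and arrive as
inputs.

## Panel selection

All non-synonymous, non-low-complexity mutations are ranked by

```
score = n_satisfied_criteria + FFPE_VAF
```

with four boolean criteria (ClinVar-pathogenic OR SIFT/PolyPhen-style
deleterious; stop-gain in a tumor suppressor; oncogene mutation with
COSMIC recurrence strictly > 3; in-house validated) and FFPE VAF in
[0, 1] as a strictly subordinate continuous term. This is the
simplest total order in which the criterion count dominates and VAF
ranks within a tier, matching the selection behaviour "highest score,
then highest FFPE VAF". Remaining ties break by genomic coordinate
and then by the remaining variant fields, making selection a total
order: the panel is invariant to input permutation and to removal of
non-selected variants, and equals a brute-force best-subset search
(property-tested against exhaustive enumeration on small inputs).
Panel size defaults to 5 and is clamped to [2, 10]; a panel with
fewer than 2 eligible mutations is emitted with a `below_minimum`
flag rather than refused. FFPE VAF ≥ 10% is exported as an advisory
plasma-detectability flag, never an exclusion.

## Positivity calling and LOD

An amplicon under 10,000X is failed (the boundary is inclusive:
exactly 10,000X passes) and excluded from both positivity and mean
VAF. A sample is ctDNA-positive when any retained tracked mutation
has VAF ≥ LOD (inclusive). Mean VAF is two-branch: the mean over
positive mutations when any exist, else the mean over all retained
tracked mutations. A sample whose amplicons all fail is
*indeterminate*, a distinct state — a false negative caused by QC
dropout must stay visible.

LOD calibration takes a titration series (defaults 3%, 0.5%, 0.1%,
0.05%, 0%), a healthy-donor panel (default 150 donors, 5 tracked
sites each) and a sorted candidate list. The per-measurement
false-positive rate of each candidate `t` is the fraction of healthy
measurements with VAF ≥ t; the chosen LOD is the smallest candidate
whose rate is below `fp_max` (default 1%). Per-measurement FP is the
primary, better-defined quantity; the per-sample variant (any tracked
site above threshold) is available as `sample_level_fp_rate`. The
calibration is invariant to permutation of the healthy panel, and the
FP rate is non-increasing in the threshold by construction.

## Longitudinal interpretation

Molecular relapse is the earliest **post-operative** positive sample;
pre-operative positivity reflects the primary tumor and never
qualifies, and a sample drawn on the surgery date counts as
pre-operative. Indeterminate calls are skipped, not treated as
negative. Lead time is `(clinical relapse − molecular relapse)` in
months of 30.4375 days (calendar-neutral; fractional months are the
natural unit for 4.0/10.5-month leads); negative values are permitted
and flagged. A positive–negative–positive sequence is reported as the
first positive plus the full call sequence, without smoothing. Serum
CEA < 5 ng/mL is normal (≥ 5 elevated, boundary inclusive on the
elevated side).

## The simulator

The generators produce every table the pipeline consumes, fully
deterministic under the config seed. Defaults are the study
conditions the pipeline assumes; each is a config field.

**Tumor profiles.** Each of 16 driver genes is mutated independently
per patient with its cohort frequency (APC 0.699, TP53 0.631, KRAS
0.398, FAT4 0.272 are reported cohort values; the remaining driver
frequencies and the 42-gene passenger pool are plausible inventions
for a colorectal panel). Bernoulli drivers make per-gene patient
frequencies exact config marginals; passengers come from the disjoint
background pool with a negative-binomial count whose mean tops the
total up to 7 mutations/patient, and 1% of patients carry no
detectable mutation. Mutation classes are i.i.d. (missense 0.723,
frameshift 0.135, nonsense 0.123, splice 0.010, in-frame 0.009).
Hotspot protein changes — KRAS G12 in 56.8% of KRAS-mutated patients,
else G13/Q61; NRAS Q61; BRAF V600E — are assigned *without* forcing
the drawn class (a frameshift at the G12 codon becomes `G12fs`), so
the class marginal is exactly the config distribution while codon-set
actionability matching still registers the hits. Annotation evidence
follows documented conditional rules (e.g. hotspots are
ClinVar-pathogenic with probability 0.9 and carry large COSMIC
counts; passengers rarely carry evidence). FFPE VAF ~ Beta(2, 4)
(mean 1/3, clonal heterozygous mutations at ≥ 60% tumor cellularity).
The per-gene class skew of real tumors (e.g. APC being
nonsense-dominated) is deliberately not modelled — it would bias the
class-marginal recovery the tests assert.

**Read counts.** Depth ~ Normal(100,000, 15,000) with 3.8% of
amplicons drawn below the 10,000X floor. Alt reads ~
Binomial(depth, p) with `p = tumor_fraction × 0.5 + e`, where 0.5 is
the heterozygosity/ploidy factor (one mutant allele per shed diploid
genome) and the per-site background error `e ~ Beta` with mean
1.5×10⁻⁴ and shape 5 (an overdispersed beta-binomial; the real
assay's error distribution is unpublished, so dispersion is a config
knob). This error model puts the per-measurement false-positive rate
at ~20% for a 0.02% threshold but ~0.1% at 0.05%, which is why
calibration lands on 0.05%: it is the smallest candidate keeping FP
below 1%. Titration mixtures carry the mutation at the stated VAF
directly (reference-standard DNA, no ploidy factor).

**Shedding and detection.** Per-patient tumor fraction is
log10-normal with σ = 0.8 and stage offsets (I −1.0, II 0.0, III
+0.1, IV +0.5 in log10 units; stage I sheds least). The single global
location parameter is solved deterministically — Gauss–Hermite
integration of a closed-form detection probability, Brent root
finding — so the marginal pre-operative detection probability equals
the config target (default 0.905) under the configured stage mix,
panel size, depth, LOD and amplicon-failure rate. The closed form
evaluates background error at its mean; dispersion matters in the
null tail, not in the signal regime being calibrated, and the
residual approximation error is well inside the binomial noise of a
200-patient cohort.

**Timelines.** Pre-op draw 0–13 days before surgery; post-op draws at
1 month and then every 6 months to an 18-month horizon. A patient
relapses with probability 2/19; the clinical relapse date is
constructed as (molecular-detection visit + lead), lead ~
U(4, 10.5) months, with shedding ramping up (doubling time 1 month)
from shortly before the detection visit — this guarantees molecular
detection precedes clinical diagnosis under the sparse 6-month visit
grid, which is the regime the monitoring logic is meant to exhibit,
not an empirical claim about relapse kinetics. Pre-op CEA is elevated
in 41.3% of patients; relapsers' CEA stays normal (CEA failed to
predict relapse in the cohort being emulated).

**What passing tests do not show.** The simulator emulates marginal
rates and the counting statistics of amplicon sequencing, not real
biology: no per-gene class skew, no correlated shedding between
visits, no UMI/duplex chemistry, no FFPE artifacts, no CHIP
leakage, fixed per-site error distribution across loci. Recovery
tests therefore validate the *pipeline's arithmetic and decision
rules* under known ground truth, not clinical performance.

## Numerical and design choices

* Thresholds follow the printed wording exactly: tumor QC strictly
  > 98% / < 1%; spectrum floor inclusive at 5%; amplicon QC inclusive
  at 10,000X; positivity inclusive at LOD; CEA elevated at ≥ 5;
  COSMIC recurrence strictly > 3.
* Pairwise gene association uses the two-sided Fisher exact test
  (safe for sparse pairs) with conditional-MLE odds ratios (0 and ∞
  permitted at zero cells; degenerate margins give OR = NaN and label
  `none`). No multiple-testing correction by default, matching the
  analysis being reproduced; `correction="bh"` enables
  Benjamini–Hochberg. The α and correction used are recorded in the
  outputs' metadata.
* ClinVar "pathogenic" and computational "deleterious" are combined
  as OR — the weaker reading; requiring both would silently drop
  well-annotated drivers lacking one source.
* Missing annotation columns default to false/0 so absent evidence
  never inflates a tracking score.
* The 5% FFPE-VAF floor applies to landscape summaries only; panel
  ranking sees all non-synonymous mutations (VAF already enters the
  score directly).
* The LOD is a single global threshold; per-amplicon overrides can be
  layered on by calling `call_sample` per measurement subset.
* Problem sizes in the test suite and acceptance script (200-patient
  cohorts, 2,000 null samples, exhaustive 2×2 enumeration to n = 30,
  ≤ 12-variant panel oracles) were chosen to keep binomial standard
  errors small relative to the effects being recovered while the
  whole suite runs in well under a minute of simulation time.

## Known limitations

* The bundled actionability table is a small seeded default with
  placeholder laboratory-evidence rows, not a curated knowledge base.
* No survival analysis, no tumor-mutational-burden normalization, no
  cross-cohort frequency comparisons; clinical relapse dates are
  inputs, never inferred.
* The artifact ships no low-complexity mask; `in_low_complexity` is
  an input flag (a BED-derived column upstream).
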