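# Methods

`plasmatriage` implements a matched tumor / germline / plasma variant-triage
analysis for targeted-panel sequencing of brain-tumor patients. This note
documents the models, the thresholds and their defaults, the synthetic data
the package generates for itself, and the numerical and design choices that
were genuinely open.

## The compartment model

Each patient contributes three sequencing compartments over one gene panel:

* **tDNA** — DNA from the resected tumor fragment;
* **gDNA** — whole-blood germline reference DNA;
* **ccfDNA** — plasma circulating cell-free DNA, sequenced deeply with
  unique molecular identifiers (UMIs).

The analysis operates entirely on per-site read counts (total depth and
alt-supporting reads, with optional per-strand splits). At a site with
germline genotype-independent error rate *e*, tumor variant allele fraction
*a* and circulating-tumor-DNA fraction *f*, the expected plasma alt
fraction is the linear mixture

    E[AF_plasma] = f · a + (1 − f) · e

since plasma DNA is a blend of tumor-shed and normal-cell fragments. The
simulator draws alt counts as Binomial(depth, p) with p given by this
mixture; no overdispersion is modeled (the real analog would be UMI-level
consensus counts, whose residual error is far below the raw read error).

## Fragment-size QC

Plasma cfDNA is mononucleosome-protected: fragment lengths concentrate in
120–220 bp with a peak near 167 bp, with smaller di- and trinucleosomal
populations near 334 and 501 bp. Lysed-leukocyte genomic DNA contaminates
profiles as fragments longer than ~2 kb. The QC verdict is:

* **fail / no_material** — total signal below a detection floor
  (`min_total_signal`, default 1 unit; signal units are deliberately
  unit-agnostic, matching electropherogram practice);
* **fail / genomic_contamination** — mass above 2000 bp exceeds
  `max_contaminant_fraction` (default 0.9) *and* the 100–500 bp cfDNA
  window carries less than `min_window_signal`;
* **pass / clean** or **pass / tolerable_contamination** otherwise,
  split at 5% long-fragment mass.

The thresholds are configurable because the underlying decision in practice
is made from exemplar electropherogram shapes, not published numbers.
Right-sided size selection zeroes abundance above 500 bp and conserves all
sub-cutoff mass; it is idempotent by construction.

Yield comparisons use classical two-tailed t-tests: Student (pooled
variance) for unpaired group comparisons, with Welch available by flag, and
the paired t-test on per-patient differences. A degenerate paired design
(all differences zero) reports p = 1 with a warning rather than an error.

The simulated yield scenarios use the study's group sizes — 8 fast-processed
vs 87 delayed samples with a 3× geometric-mean effect, and 19 paired
pre/post-surgery samples with a 2× effect — under multiplicative lognormal
noise (σ = 0.5 on the log scale, a typical biological coefficient of
variation for cfDNA yield; 20% relative noise on the paired differences).

## Somatic calling

Each site's tumor and germline counts form the 2×2 table
(alt, ref) × (tumor, germline), tested with the two-sided Fisher exact
test. The two-sided p-value is the standard minimum-likelihood convention:
the total probability of tables (at fixed margins) no more probable than
the observed one.

For tables with total N ≤ 512 the test is computed in **exact integer
arithmetic**: conditional table probabilities are proportional to
C(r₁,k)·C(r₂,c₁−k), so comparisons and sums are exact and the result is a
rational number converted to float only at the end. Larger tables use the
hypergeometric distribution in floating point with the conventional 1e-7
relative tie tolerance. The strand-bias test reuses the same core on the
(alt, ref) × (forward, reverse) table.

Status assignment:

* **somatic** — Fisher p ≤ 0.05 (configurable; the conventional cutoff),
  germline AF < 1% and tumor AF ≥ 1%;
* **germline** — germline AF in the heterozygous band [0.25, 0.75] and
  tumor concordant (no significant departure);
* **LOH** — germline heterozygous but tumor AF outside the band with a
  significant test;
* **unknown** — anything else.

Retention filters are applied with literal boundary semantics ("at least"
is ≥, "less than" is <): coverage ≥ 10 reads in both compartments, ≥ 3
tumor alt reads, tumor AF ≥ 1%, germline AF < 1%, and no strand bias
(strand Fisher p < 0.05 **and** ≥ 90% of alt reads on one strand). Every
rule outcome is appended to the call's trail, so retained + discarded =
input holds at every stage and each discarded call carries its reasons.

Annotation-based filters drop calls that are catalogued with population
allele frequency above 0.001 (so rare catalogued pathogenic variants
survive), non-coding calls, and SIFT-tolerated calls. SIFT convention:
damaging = score < 0.05 (the standard direction); a `sift_inverted` switch
selects the opposite reading for compatibility with reports that print the
inequality the other way round. Variants absent from the catalog are
retained.

## Plasma ctDNA detection

Plasma evidence is counted in UMI-consensus molecules: reads sharing a UMI
tag are one pre-PCR molecule, and each family votes by strict majority
(ties are discarded — base qualities are out of scope, so there is no
principled tie-break). Consensus depth is the number of unambiguous
families. Majority voting is what licenses a low detection threshold: with
per-duplicate error 1e-3 and ~3 duplicates per family, the residual
consensus error is ~3×10⁻⁶, so three alt consensus molecules are strong
evidence even at depth 1000.

A tumor-somatic variant is **detected** in plasma when ≥ 3 alt consensus
molecules support it and the germline compartment is clean (gDNA AF < 1%,
mirroring the somatic rule). There is deliberately **no plasma AF floor**:
true detections run down to AF ≈ 0.009 at deep consensus coverage, and the
1% AF rule demonstrably applies to the tumor compartment only.

Diagnosis labels map to classes through a small controlled vocabulary:
any WHO-graded glioma histology (glioblastoma, astrocytoma,
oligodendroglioma, oligoastrocytoma, xanthoastrocytoma) → *glioma*;
lymphomas → *pcnsl*; metastatic carcinomas → *metastasis*.

## Triage of plasma-only variants

Diffuse gliomas are regionally heterogeneous; plasma integrates DNA from
the entire lesion, so a variant seen in ccfDNA but not in the resected
fragment is not automatically an artifact. Records qualify for triage when
plasma has ≥ 2 alt consensus molecules (deep-plasma callers report
variants from 2 supporting molecules upward, and real triage candidates
occur at that support level) and the germline
is absent — strictly (gDNA alt = 0) for pathogenicity claims, or relaxed
(gDNA alt ≤ 3 and AF < 10%) for cohort-confirmation comparisons, where a
few stray germline reads at low depth are tolerated.

Tier assignment is a total function with a fixed first-match rule order:

1. `CTDNA_CONFIRMED` — same identity among the same patient's tumor
   somatic calls;
2. `COHORT_CURRENT_CONFIRMED` — identity somatic in another patient of the
   current cohort;
3. `COHORT_PRIOR_CONFIRMED` — identity in the prior-cohort somatic catalog;
4. `PATHOGENIC_CCFDNA_ONLY` — ClinVar-style pathogenic / likely-pathogenic
   annotation, or COSMIC-registered and population AF ≤ 0.001 (this
   rarity arm is what admits "uncertain significance" variants with AFs of
   10⁻⁴–10⁻⁵ while excluding common polymorphisms);
5. `CARRIER_BENIGN` — benign annotation (a germline carrier allele seen
   through plasma);
6. `DISCARDED`.

Variant identity is matched by coordinates when available and by rsID
otherwise, because report tables differ in which identifiers they print.

## Copy-number calling

Per-exon mean depths for test, matched-normal and reference-normal tracks
are each scaled to panel-wide mean 1; per-exon log2(test/control) ratios
are thresholded at log2(1.25) ≈ +0.32 for gains (≥ 2.5 copies in a diploid
background) and log2(0.75) ≈ −0.42 for losses (≤ 1.5 copies); adjacent
same-state exons of a gene merge into one call. Germline events are calls
of matched-normal vs reference-normal; a test-side call coinciding with an
identical-state germline call is reported as germline in origin. Exons with
zero control depth are masked with a reason, never silently dropped.

Hidden-Markov segmentation, GC-content correction, tumor-purity correction
and B-allele-frequency phasing are deliberately out of scope: the caller is
a documented, testable ratio-threshold method.

**Known limitation.** Panel-mean normalization assumes most of the panel is
copy-neutral. If a large fraction of the panel is amplified, the mean
shifts and moderate gains (3 copies) become undetectable — with 4 of 10
genes altered the bias is ≈ −0.38 log2 units. The recovery tests therefore
inject one focal event per sample, which is also the realistic scenario for
focal tumor amplifications; median-robust normalization would be the
upgrade path if heavily altered panels were in scope.

## Synthetic cohort

The generator emulates the study's structure: 84 patients by default (the
diagnosis mix approximates 80 gliomas, 2 CNS lymphomas, 2 metastases), 20
germline heterozygous sites, 8 clonal somatic sites (AF uniform in
[0.2, 0.7]) and 2 plasma-only sites per patient, per-base error 1e-3, mean
depths 150/150/1500 for gDNA/tDNA/ccfDNA (the plasma panel is sequenced
roughly an order of magnitude deeper), and ctDNA fractions uniform in
[0, 0.2] (plasma ctDNA burden in brain tumors is low and often zero).
Fragment-length profiles mix mono/di/trinucleosomal peaks at weights
0.80/0.15/0.05 (the di/tri split is a modeling choice; only their existence
is established) plus an optional >2 kb contaminant.

Determinism: every sampling call is driven by a `numpy` Generator spawned
from `(cohort seed, patient index)`, so identical spec + seed reproduces
byte-identical outputs and per-patient trios are independent of cohort
size. No global random state is touched.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: mapping and alignment artifacts, indels and
multi-allelic sites, GC- and fragment-length-dependent coverage bias
beyond a shared per-exon capture efficiency, PCR chimeras, subclonal tumor
structure, and contamination between compartments.

## Problem sizes in the test suite

Stochastic properties run at 200 replicate seeds (100 for copy-number
recovery), matching the replication the properties are stated at; the
exact-test oracle sweep enumerates all 246,016 tables with margins ≤ 30.
The full suite runs in well under a minute on one CPU.
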