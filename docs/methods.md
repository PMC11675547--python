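# Methods

## Scope and shape

`varpoints` models the re-interpretation of conflicting ClinVar *BRCA1*
missense variants with two points-based ACMG/AMP engines and the statistics
used to compare them. The engines are deterministic rule systems, not
fitted models: for a fixed variant, annotation bundle and configuration the
output is always identical, and all randomness in the package lives in the
synthetic cohort generator. Classification operates at the protein level
(HGVS p. and a 1-based amino-acid position); genomic coordinates,
transcripts and non-missense consequences are out of scope.

## Points model and category tables

Evidence strengths carry the standard point magnitudes — supporting 1,
moderate 2, strong 4, very strong 8 — signed by direction. Category tables:
gene-specific PV ≥ 10 / LPV 6–9 / VUS 0–5 / LBV −5…−1 / BV ≤ −6; automated
PV ≥ 10 / LPV 6–9 / VUS 0–5 / LBV −6…−1 / BV ≤ −7. The two published
tables genuinely disagree at a total of −6 (benign under the gene-specific
table, likely benign under the automated one) and both are implemented
verbatim; the divergence is pinned by a boundary fixture rather than
reconciled.

BA1 has no natural point value in a summation scheme. It is carried at −8
points so totals stay well-defined, but its category effect is an explicit
stand-alone override recorded on the result, applied before any other rule.

### Gene-specific overrides

* **PM2 exclusion.** When PM2 (supporting) is the only pathogenic-direction
  element and the total *without* it already falls in benign territory, PM2
  is dropped from the total. Read strictly: PM2 itself does not count as
  "additional pathogenicity-related evidence", so a lone PM2 can never hold
  an otherwise-benign variant out of LBV/BV.
* **VUS demotion.** A benign-territory total carrying ≥ 2
  pathogenic-direction elements (any strength) is returned as VUS. Both
  readings — whether PM2 counts itself, whether supporting-only elements
  count — were open; the implementation counts every pathogenic-direction
  element including PM2, which is the conservative (uncertainty-preserving)
  choice. Because the exclusion rule only fires when PM2 is the *sole*
  pathogenic element, the two overrides can never fire together.

Evidence lists are canonically sorted by code before combination, so results
are order-independent; duplicate codes are rejected.

## Evidence criteria — gene-specific engine

* **Population (BA1/BS1/PM2).** The observed allele count is tested against
  the maximum tolerated count at each threshold (BA1 0.001, BS1 0.0001):
  the one-sided 95% quantile of Poisson(threshold × allele number), the
  convention of the CardioDB-style allele-frequency calculators
  (`qpois(0.95, AN·AF)`). "Exceeds" is strict: a count exactly at the
  tolerated count does not trigger benign evidence. Counts not exceeding
  the BS1 tolerance — including zero, i.e. absence from controls — yield
  PM2 at supporting strength (a config switch raises absence to moderate).
  With only a point-estimate frequency available the frequency itself is
  compared; with no population data at all, *no* evidence is emitted:
  absence of data is "insufficient", never PM2 and never benign. (The
  alternative reading — missing data as PM2 — was considered and rejected
  because an empty annotation bundle must classify to VUS with zero
  evidence, not acquire a point from ignorance.)
* **Functional (PS3/BS3).** The assay's evidence grade is an input
  (`assay_strength`), mirroring guidance that assigns strengths per
  validated assay; any functional result without a grade is rejected, for
  normal results as well as abnormal, since an ungraded assay cannot be
  weighed in either direction. Splice-effect assay results map to PS3 with
  the splice annotation retained on the assignment.
* **Same residue (PM5).** Moderate when the query REVEL is ≥ the reference
  variant's and the reference is an established call; supporting when the
  reference is an LPV with limited reports or the query scores lower.
  Missing REVEL on either side falls back to supporting. One PM5 at the
  strongest applicable grade.
* **Multifactorial (PP5/BP6).** Published likelihood ratios map through the
  Bayesian-calibration bins (supporting ≈ 2.08, moderate ≈ 4.33, strong
  ≈ 18.7, very strong ≈ 350; reciprocals for benign, capped at strong).
  The bins are config data, not hard-coded science.
* **In silico (PP3/BP4).** REVEL > 0.7 → PP3 supporting; REVEL < 0.4 → BP4
  supporting; both strict, the 0.4–0.7 band silent.
* **Location (PM1/BP1).** Domains default to RING 1–101, COILED-COIL
  1391–1424, BRCT 1650–1863. (A variant-location summary elsewhere in the
  source guidance prints RING 2–101 and BRCT 1650–1857; the procedural
  values are the default and the alternative is expressible in config.)
  PM1 is supporting in-domain, moderate at configured critical residues
  (empty by default — no canonical list is published). BP1 applies outside
  all domains when the predicted splice impact is < 0.2; a missing splice
  prediction counts as "no predicted effect" by default (most conflicting
  variants lack splice annotations), switchable to blocking.
* **Case-control (PS4).** OR ≥ 10 (inclusive) triggers PS4 at strong by
  default; the guidance permits very strong…supporting, so the strength is
  configurable.
* **PS1.** Triggered by an input flag asserting an identical amino-acid
  change with an established pathogenic classification, at strong; no
  modulation rules are defined.

## Automated engine emulation

The automated engine is an emulation of the described generic point system,
not a re-implementation of any proprietary tool. Every behaviour beyond
the plain point system is an explicit toggle tied to an observed output
pattern: BP3 applied to repeat-region missense variants
(`apply_bp3_missense`, driven by a `repeat_region` input flag), BP1
extended to all out-of-domain missense without a splice guard
(`apply_bp1_extended`), PM5 escalated to strong for a pathogenic
same-residue reference (`allow_pm5_strong`), and benign computational
evidence graded up to strong (`graded_bp4`). MetaRNN calibration bins
default to a published-style graded mapping (supporting ≥ 0.75, moderate
≥ 0.85, strong ≥ 0.94; benign ≤ 0.30 / 0.15 / 0.05) and are config data.
Functional-assay evidence is off by default — automated classification of
the discordant cases characteristically lacked applied functional evidence
— and can be enabled. Population evidence shares the frequency machinery
and, because both engines read the same annotation field, the same default
thresholds; the real tools differ chiefly in *which* gnomAD subset they
read, which is upstream of this package's inputs.

With all toggles off and identical evidence lists, the engines' totals are
identical and their categories differ only at −6.

## Conflict, consolidation and concordance

Five-tier calls consolidate as PV/LPV, VUS, BV/LBV. A variant is
*conflicting* when ≥ 2 assertion-criteria submissions span ≥ 2 consolidated
tiers — PV vs LPV is not a conflict — and only assertion-criteria
submissions are counted anywhere (conflicts, vote fractions, consensus),
extending the published counting rule uniformly. *Consensus* at a later
snapshot means all countable submissions consolidate to one tier.

Concordance is the confusion-matrix trace over the total, with an exact
Clopper–Pearson interval (`statsmodels`, method `beta`). The published
interval for the real cohort's headline rate is not reproducible by
standard binomial methods (the software settings behind it are unstated),
so only the rate itself is asserted. Printed percentages use one decimal,
ties rounded away from zero — the convention that reproduces every
published table value.

Submitter-stratified agreement uses three nested strata per analysed tier:
a voting majority (> 50%), a non-majority minority (≤ 50% but at least one
voter — required for the published stratum sizes to nest, 21 + 34 = 55),
and their union.

## Packaged published counts

`datasets.py` carries the published summary tables as code literals: the
per-engine tier counts, the stratified (n, matches) pairs, the 17
consensus-update rows, and a cross-classification grid. The published
figure's discordant cells are internally inconsistent with the marginals by
one variant; the packaged grid is the unique completion consistent with
both engines' marginal counts, the 265 concordant total and the 138-variant
automated-benign/gene-specific-VUS count printed in the accompanying
analysis. Individual discordant cells are treated as reconstruction and
never asserted in tests; only directly published quantities (marginals,
265/450) are.

## Synthetic cohort generator

The generator emulates the *structure* of the real conflicting cohort, with
defaults chosen once to mirror the published cohort description:

* 450 variants, positions drawn with weights RING 0.35 / BRCT 0.40 /
  coiled-coil 0.05 / elsewhere 0.20 (the real cohort concentrates in RING
  and BRCT);
* submitter counts on [2, 15] with weights elevated at 2, 3 and 5
  (91 : 85 : 73 as published, smooth tail elsewhere), assertion criteria
  present for 90% of submissions;
* every first-snapshot submission set conflicting **by construction**
  (tier assignments rejection-sampled until they span two consolidated
  tiers), so stage tests get exactly n conflicting records;
* a latent pathogenic indicator (rate 0.2, matching the ~11% pathogenic
  calls plus borderline mass) drives correlated REVEL/MetaRNN draws via a
  Gaussian copula (ρ = 0.7) over pathogenic-leaning Beta(8, 2) and
  benign-leaning Beta(1.5, 5) components;
* allele counts zero-inflated (half absent from controls) with log-uniform
  rare frequencies up to 3×10⁻⁴, allele numbers 40–90k;
* sparse evidence: functional 15%, multifactorial 8%, case-control 4%,
  same-residue references 10%, splice predictions 30%, repeat-region flags
  at the 57/450 published rate;
* a second snapshot resolving 17/450 ≈ 3.8% of variants to a single tier,
  modelling the two extraction dates as a resolve-fraction process with no
  submitter-level temporal dynamics.

What the generator does *not* emulate: real mutational spectra, gnomAD
subpopulation structure, submitter identity correlations, or any coupling
between the latent indicator and the true (unknown) pathogenicity of real
variants. Passing pipeline tests on synthetic cohorts therefore
demonstrates the machinery's correctness and determinism, not clinical
accuracy on real data.

Boundary fixtures are hand-curated (variant, bundle, expected-category)
triples pinning every decision threshold: REVEL 0.39/0.40/0.70/0.71,
splice 0.19/0.20, OR 9.9/10, allele counts one either side of both
frequency tolerances at AN = 100 000 (tolerated counts 117 and 15), and
point totals at every category boundary including the −6 divergence.

## Numerical choices

* Poisson quantile via `scipy.stats.poisson.ppf`; tests verify equivalence
  with direct probability-mass summation for all means ≤ 500. The quantile
  reading (smallest c whose cumulative mass reaches the confidence) is the
  calculator convention; thresholds are strict on the observed count.
* Submitter vote fractions use exact rational arithmetic
  (`fractions.Fraction`), so the three tier fractions sum to exactly 1 and
  the > 50% stratum boundary has no floating-point ambiguity.
* Percentages: `Decimal` half-away-from-zero at one decimal.
* Degenerate inputs are rejected with the offending value named: empty
  evidence lists are valid (total 0 → VUS), empty confusion matrices and
  zero countable submissions are errors, missing population data is a
  distinct "insufficient data" outcome, never `False`.

## Problem sizes

The test suite and acceptance script run cohorts of 450 variants (the
published cohort size) for end-to-end checks, 10 000 draws for the
submitter-count distribution check, exhaustive subset enumeration over
6-element evidence pools (64 subsets per pool), and all integer Poisson
means up to 500; the whole suite completes in well under a minute.

## Known limitations

* The automated engine's toggles reproduce observed behaviours, not the
  proprietary trigger logic that caused them; per-version drift of the real
  tool is out of scope.
* PS1 and PM1-critical-residue inputs are flags/config supplied by the
  user; the package does not derive them from sequence databases.
* Real ClinVar exports need a thin adapter to the package's TSV dialect;
  VCF ingest is limited to variant identity and is not wired into the
  engines.
* The splicing-variant and indel evidence codes (PVS1, PM4, BP7) and the
  newer ClinGen ENIGMA specification are deliberately not implemented.
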