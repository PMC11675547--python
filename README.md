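# varpoints

Points-based ACMG/AMP classification engines for *BRCA1* missense variants,
with ClinVar conflict extraction, cross-engine concordance analysis and a
synthetic cohort generator.

## The problem

ClinVar aggregates variant classifications from many submitters, and for
*BRCA1* missense variants those submitters frequently disagree: the same
variant is called pathogenic (PV), likely pathogenic (LPV), uncertain (VUS),
likely benign (LBV) or benign (BV) by different laboratories. Conflicting
interpretations complicate decisions about PARP-inhibitor eligibility,
risk-reducing surgery and cascade testing, so clinical laboratories
re-interpret such variants with structured evidence frameworks.

`varpoints` implements two such frameworks as deterministic rule engines and
the statistics used to compare them:

* **a gene-specific engine** following the CanVIG-UK BRCA1/BRCA2 guidance —
  population-frequency evidence against maximum-tolerated allele counts,
  functional-assay codes (PS3/BS3), same-residue precedent (PM5 graded by
  REVEL), multifactorial likelihood ratios (PP5/BP6), REVEL thresholds
  (PP3/BP4), domain location (PM1/BP1 with a splice guard) and case-control
  enrichment (PS4);
* **an automated generic engine** emulating VarSome-style interpretation —
  MetaRNN-calibrated computational evidence graded supporting→strong, BP3 on
  repeat-region missense variants, extended BP1, PM5 escalation to strong,
  and no curator overrides.

It is aimed at clinical-genetics analysts and methodologists who want to
study *why* gene-specific and generic automated classification disagree, on
reproducible synthetic cohorts or on their own annotation tables.

## The scoring model

Each triggered criterion contributes signed points by evidence strength —
supporting ±1, moderate ±2, strong ±4, very strong ±8 (benign direction
negative) — and the total *S* maps to a tier:

| Engine        | PV     | LPV   | VUS   | LBV        | BV       |
|---------------|--------|-------|-------|------------|----------|
| gene-specific | S ≥ 10 | 6–9   | 0–5   | −5 … −1    | S ≤ −6   |
| automated     | S ≥ 10 | 6–9   | 0–5   | −6 … −1    | S ≤ −7   |

BA1 (allele frequency above the stand-alone threshold) forces BV regardless
of the total. The gene-specific engine adds two curator overrides: a
supporting PM2 is excluded from the total when it is the only
pathogenic-direction element and the rest of the evidence is already benign,
and a benign-territory total is demoted to VUS when two or more
pathogenic-direction elements were applied.

Population evidence uses the filtering-allele-frequency idea: the observed
gnomAD allele count is compared with the 95% one-sided Poisson quantile of
`threshold × allele_number` (thresholds 0.001 for BA1, 0.0001 for BS1).

For comparison, five-tier calls are consolidated into PV/LPV, VUS and
BV/LBV; agreement is the trace of the 3×3 confusion matrix with an exact
Clopper–Pearson interval.

## Worked example

```python
from varpoints import (
    AnnotationBundle, VariantRecord, Strength,
    classify_variant_canvig, classify_variant_auto,
)

variant = VariantRecord(
    variant_id="ex1", gene="BRCA1", hgvs_c="c.5408G>C",
    hgvs_p="p.Gly1803Ala", protein_position=1803,
)
bundle = AnnotationBundle(
    af=0.0, allele_count=0, allele_number=60_000,   # absent from controls
    revel=0.85, metarnn=0.88,                        # damaging in silico
    functional_result="abnormal", assay_strength=Strength.STRONG,
)

canvig = classify_variant_canvig(variant, bundle)
auto = classify_variant_auto(variant, bundle)
print(canvig.category.name, canvig.total_points, canvig.codes())
print(auto.category.name, auto.total_points, auto.codes())
```

prints

```
LPV 7 ('PM1', 'PM2', 'PP3', 'PS3')
VUS 3 ('PM2', 'PP3')
```

The gene-specific engine reaches LPV (PM1 supporting +1 in the BRCT domain,
PM2 supporting +1, PP3 supporting +1, PS3 strong +4 = 7 points); the
automated engine, lacking applied functional evidence and domain criteria,
stays at VUS (PM2 +1 plus a MetaRNN-graded moderate PP3 +2, totalling 3).
Exactly this pattern — functional
evidence lifting gene-specific calls that automated interpretation leaves at
VUS — drives most pathogenic-side discordance between the two approaches.

A shell pipeline over TSV tables is also available:

```bash
varpoints simulate --seed 1 --n 450 --out-dir run/
varpoints classify --input run/annotations.tsv --engine both --out-dir run/
varpoints compare --canvig run/classifications_canvig.tsv \
    --auto run/classifications_auto.tsv \
    --submissions run/submissions_first.tsv --out-dir run/
varpoints consensus --canvig run/classifications_canvig.tsv \
    --auto run/classifications_auto.tsv \
    --snapshot2 run/submissions_second.tsv --out-dir run/
```

## Layout

```
src/varpoints/
  model.py        shared domain types (tiers, evidence, results)
  popfreq.py      maximum-tolerated allele-count test
  canvig.py       gene-specific engine
  autoengine.py   automated generic engine (emulation toggles)
  clinvar.py      submission-table ingest, conflict & consensus logic
  concordance.py  confusion matrix, concordance, strata, consensus reports
  datasets.py     published summary count tables (package data)
  simulate.py     synthetic cohorts and boundary fixtures
  tables.py       TSV IO
  cli.py          varpoints command-line pipeline
```

See `docs/methods.md` for the modelling choices and their rationale.
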