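"""Synthetic conflicting-variant cohorts with the structure the analyses assume.

Generates a cohort of BRCA1 missense variants that mirrors the published
conflicting-variant population: positions concentrated in the RING and
BRCT domains, two to fifteen ClinVar submitters per variant with modes at
two, three and five, every first-snapshot submission set conflicting at
the three-tier level by construction, sparse functional and
multifactorial evidence, correlated REVEL/MetaRNN scores drawn from
pathogenic- and benign-leaning mixture components via a Gaussian copula,
and a zero-inflated rare-frequency model for gnomAD allele counts.  A
second snapshot resolves a small fraction of variants to consensus.

Also provides hand-curated boundary fixtures that pin every decision
threshold of both engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
from scipy import stats

from .canvig import BRCA1_DOMAINS, DomainRegion
from .clinvar import VariantSubmissionSet, is_conflicting
from .model import (
    AnnotationBundle,
    Consequence,
    FiveTier,
    SameResidueRef,
    Strength,
    SubmissionRecord,
    VariantRecord,
    consolidate,
)

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()

SNAPSHOT_FIRST = date(2022, 12, 20)
SNAPSHOT_SECOND = date(2024, 5, 1)


@dataclass(frozen=True)
class CohortSpec:
    """Statistical recipe for a synthetic conflicting-variant cohort.

    Defaults reproduce the structure of the real 450-variant cohort:
    domain weights concentrating mass in RING and BRCT, submitter counts
    in [2, 15] with elevated mass at 2, 3 and 5 (91, 85 and 73 of 450),
    roughly one variant in five leaning pathogenic, sparse functional
    (15%) and multifactorial (8%) evidence, REVEL/MetaRNN correlation
    0.7, and 4% of variants (17 of 450) resolving to consensus at the
    second snapshot.
    """

    n_variants: int = 450
    seed: int = 0
    domain_weights: dict[str, float] = field(
        default_factory=lambda: {
            "RING": 0.35,
            "BRCT": 0.40,
            "COILED-COIL": 0.05,
            "outside": 0.20,
        }
    )
    submitter_count_weights: dict[int, float] = field(
        default_factory=lambda: {
            2: 91, 3: 85, 4: 40, 5: 73, 6: 30, 7: 25, 8: 20, 9: 16,
            10: 14, 11: 12, 12: 10, 13: 9, 14: 8, 15: 7,
        }
    )
    pathogenic_fraction: float = 0.20
    score_correlation: float = 0.7
    presence: dict[str, float] = field(
        default_factory=lambda: {
            "af": 0.85,
            "revel": 0.95,
            "metarnn": 0.95,
            "splice": 0.30,
            "functional": 0.15,
            "lr": 0.08,
            "case_control": 0.04,
            "same_residue": 0.10,
        }
    )
    zero_count_fraction: float = 0.5
    repeat_region_fraction: float = 57 / 450
    resolve_fraction: float = 17 / 450
    assertion_criteria_rate: float = 0.9
    domains: tuple[DomainRegion, ...] = BRCA1_DOMAINS
    max_conflict_tries: int = 1000

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if any(w < 0 for w in self.domain_weights.values()) or not any(
            self.domain_weights.values()
        ):
            raise ValueError("domain weights must be non-negative, not all zero")
        counts = self.submitter_count_weights
        if any(k < 2 or k > 15 for k in counts):
            raise ValueError("submitter counts must lie in [2, 15]")
        if not any(v > 0 for v in counts.values()):
            raise ValueError("submitter count weights must not all be zero")
        for name, rate in {
            "pathogenic_fraction": self.pathogenic_fraction,
            "resolve_fraction": self.resolve_fraction,
            "zero_count_fraction": self.zero_count_fraction,
            "assertion_criteria_rate": self.assertion_criteria_rate,
            **self.presence,
        }.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {name} must lie in [0, 1], got {rate}")
        if not (-1.0 < self.score_correlation < 1.0):
            raise ValueError("score_correlation must lie in (-1, 1)")


@dataclass
class SyntheticCohort:
    variants: list[VariantRecord]
    bundles: list[AnnotationBundle]
    snapshot_first: list[VariantSubmissionSet]
    snapshot_second: list[VariantSubmissionSet]


def _draw_position(rng: np.random.Generator, spec: CohortSpec) -> int:
    names = list(spec.domain_weights)
    weights = np.array([spec.domain_weights[n] for n in names], dtype=float)
    choice = rng.choice(len(names), p=weights / weights.sum())
    name = names[choice]
    if name == "outside":
        domains = sorted(spec.domains, key=lambda d: d.start_aa)
        gaps: list[tuple[int, int]] = []
        cursor = 1
        for dom in domains:
            if dom.start_aa > cursor:
                gaps.append((cursor, dom.start_aa - 1))
            cursor = dom.end_aa + 1
        gaps.append((cursor, 1863))
        sizes = np.array([hi - lo + 1 for lo, hi in gaps], dtype=float)
        lo, hi = gaps[rng.choice(len(gaps), p=sizes / sizes.sum())]
        return int(rng.integers(lo, hi + 1))
    dom = next(d for d in spec.domains if d.name == name)
    return int(rng.integers(dom.start_aa, dom.end_aa + 1))


def _correlated_scores(
    rng: np.random.Generator, pathogenic: bool, rho: float
) -> tuple[float, float]:
    """REVEL/MetaRNN pair via a Gaussian copula over mixture components."""
    z1 = rng.standard_normal()
    z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal()
    u1, u2 = stats.norm.cdf([z1, z2])
    a, b = (8.0, 2.0) if pathogenic else (1.5, 5.0)
    revel = float(stats.beta.ppf(u1, a, b))
    metarnn = float(stats.beta.ppf(u2, a, b))
    return min(max(revel, 0.0), 1.0), min(max(metarnn, 0.0), 1.0)


_TIER_WEIGHTS = {
    True: {FiveTier.PV: 0.30, FiveTier.LPV: 0.25, FiveTier.VUS: 0.30,
           FiveTier.LBV: 0.10, FiveTier.BV: 0.05},
    False: {FiveTier.PV: 0.02, FiveTier.LPV: 0.05, FiveTier.VUS: 0.38,
            FiveTier.LBV: 0.35, FiveTier.BV: 0.20},
}


def _draw_conflicting_tiers(
    rng: np.random.Generator, n_sub: int, pathogenic: bool, max_tries: int
) -> list[FiveTier]:
    tiers = list(_TIER_WEIGHTS[pathogenic])
    weights = np.array([_TIER_WEIGHTS[pathogenic][t] for t in tiers])
    weights = weights / weights.sum()
    for _ in range(max_tries):
        draw = [tiers[i] for i in rng.choice(len(tiers), size=n_sub, p=weights)]
        if len({consolidate(t) for t in draw}) >= 2:
            return draw
    raise RuntimeError(
        "could not draw a conflicting tier assignment; the tier weights "
        "leave essentially no conflict probability"
    )


def _make_bundle(
    rng: np.random.Generator, spec: CohortSpec, pathogenic: bool
) -> AnnotationBundle:
    pres = spec.presence
    fields: dict = {}

    if rng.random() < pres["af"]:
        an = int(rng.integers(40_000, 90_000))
        if rng.random() < spec.zero_count_fraction:
            ac = 0
        else:
            log_af = rng.uniform(math.log10(1e-6), math.log10(3e-4))
            ac = min(an, max(1, int(round(10**log_af * an))))
        fields.update(
            af=ac / an, allele_count=ac, allele_number=an
        )

    revel, metarnn = _correlated_scores(rng, pathogenic, spec.score_correlation)
    if rng.random() < pres["revel"]:
        fields["revel"] = round(revel, 3)
    if rng.random() < pres["metarnn"]:
        fields["metarnn"] = round(metarnn, 3)
    if rng.random() < pres["splice"]:
        fields["splice_score"] = round(float(rng.beta(1.2, 8.0)), 3)

    if rng.random() < pres["functional"]:
        roll = rng.random()
        if pathogenic:
            result = "abnormal" if roll < 0.75 else ("splice_effect" if roll < 0.85 else "intermediate")
        else:
            result = "normal" if roll < 0.8 else "intermediate"
        if result != "intermediate":
            fields["functional_result"] = result
            fields["assay_strength"] = [
                Strength.STRONG, Strength.MODERATE, Strength.SUPPORTING
            ][rng.choice(3, p=[0.5, 0.3, 0.2])]
        else:
            fields["functional_result"] = "intermediate"

    if rng.random() < pres["lr"]:
        mu = 1.5 if pathogenic else -1.2
        fields["multifactorial_lr"] = float(np.exp(rng.normal(mu, 1.5)))
    if rng.random() < pres["case_control"]:
        mu = math.log(12.0) if pathogenic else math.log(2.0)
        fields["case_control_or"] = float(np.exp(rng.normal(mu, 0.5)))
    if rng.random() < pres["same_residue"]:
        ref_cls = FiveTier.PV if rng.random() < 0.6 else FiveTier.LPV
        fields["same_residue_refs"] = (
            SameResidueRef(
                hgvs_p="p.ref",
                classification=ref_cls,
                revel=round(float(rng.beta(8.0, 2.0)), 3),
                limited_reports=bool(rng.random() < 0.3),
            ),
        )
    if rng.random() < spec.repeat_region_fraction:
        fields["repeat_region"] = True
    return AnnotationBundle(**fields)


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate a reproducible cohort; ``seed`` overrides the spec's seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    sub_counts = sorted(spec.submitter_count_weights)
    sub_weights = np.array(
        [spec.submitter_count_weights[k] for k in sub_counts], dtype=float
    )
    sub_weights = sub_weights / sub_weights.sum()

    variants: list[VariantRecord] = []
    bundles: list[AnnotationBundle] = []
    first: list[VariantSubmissionSet] = []
    second: list[VariantSubmissionSet] = []

    n_resolve = int(round(spec.resolve_fraction * spec.n_variants))
    resolve_idx = set(
        rng.choice(spec.n_variants, size=n_resolve, replace=False).tolist()
    ) if n_resolve else set()

    for i in range(spec.n_variants):
        pathogenic = bool(rng.random() < spec.pathogenic_fraction)
        position = _draw_position(rng, spec)
        ref_aa, alt_aa = rng.choice(len(_AA3), size=2, replace=False)
        vid = f"SYN{i + 1:05d}"
        variant = VariantRecord(
            variant_id=vid,
            gene="BRCA1",
            hgvs_c=f"c.{position * 3 - 1}G>A",
            hgvs_p=f"p.{_AA3[ref_aa]}{position}{_AA3[alt_aa]}",
            protein_position=position,
            consequence=Consequence.MISSENSE,
        )
        bundle = _make_bundle(rng, spec, pathogenic)

        n_sub = int(sub_counts[rng.choice(len(sub_counts), p=sub_weights)])
        tiers = _draw_conflicting_tiers(
            rng, n_sub, pathogenic, spec.max_conflict_tries
        )
        criteria = [bool(rng.random() < spec.assertion_criteria_rate) for _ in tiers]
        # the conflict was drawn over all submitters; make it countable by
        # guaranteeing the first two carry assertion criteria, and keep the
        # first two spanning two tiers
        criteria[0] = criteria[1] = True
        if consolidate(tiers[0]) is consolidate(tiers[1]):
            other = next(
                t for t in tiers if consolidate(t) is not consolidate(tiers[0])
            )
            tiers[1] = other
        subs_first = [
            SubmissionRecord(
                variant_id=vid,
                submitter_id=f"submitter{int(rng.integers(1, 200)):03d}",
                classification=t,
                assertion_criteria=c,
                snapshot_date=SNAPSHOT_FIRST,
            )
            for t, c in zip(tiers, criteria)
        ]
        if i in resolve_idx:
            consensus_tier = [t for t in tiers if t is not FiveTier.VUS]
            target = (
                consensus_tier[0] if consensus_tier else FiveTier.VUS
            )
            subs_second = [
                SubmissionRecord(
                    variant_id=s.variant_id,
                    submitter_id=s.submitter_id,
                    classification=target,
                    assertion_criteria=s.assertion_criteria,
                    snapshot_date=SNAPSHOT_SECOND,
                )
                for s in subs_first
            ]
        else:
            subs_second = [
                SubmissionRecord(
                    variant_id=s.variant_id,
                    submitter_id=s.submitter_id,
                    classification=s.classification,
                    assertion_criteria=s.assertion_criteria,
                    snapshot_date=SNAPSHOT_SECOND,
                )
                for s in subs_first
            ]

        variants.append(variant)
        bundles.append(bundle)
        first.append(VariantSubmissionSet(variant=variant, submissions=subs_first))
        second.append(VariantSubmissionSet(variant=variant, submissions=subs_second))

    assert all(is_conflicting(s) for s in first)
    return SyntheticCohort(
        variants=variants,
        bundles=bundles,
        snapshot_first=first,
        snapshot_second=second,
    )


@dataclass(frozen=True)
class BoundaryFixture:
    """One curated (variant, bundle) pair with expected categories per engine.

    ``expected_canvig`` / ``expected_auto`` are None when the fixture does
    not target that engine.
    """

    name: str
    variant: VariantRecord
    bundle: AnnotationBundle
    expected_canvig: FiveTier | None = None
    expected_auto: FiveTier | None = None


def _fixture_variant(name: str, position: int) -> VariantRecord:
    return VariantRecord(
        variant_id=f"fix_{name}",
        gene="BRCA1",
        hgvs_c="c.1A>G",
        hgvs_p=f"p.Xaa{position}Yaa",
        protein_position=position,
    )


def generate_boundary_fixtures() -> list[BoundaryFixture]:
    """Deterministic fixtures pinning every decision threshold of both engines.

    Covers the REVEL 0.4/0.7 strict cut-offs, the splice 0.2 guard, the
    odds-ratio 10 inclusive threshold, allele counts one either side of
    the stand-alone and strong benign frequency tolerances (allele number
    100000: tolerated counts 117 and 15 at 95% confidence), and point
    totals at every category boundary — including the -6 total, benign
    under the gene-specific table but likely benign under the automated
    table.
    """
    fx: list[BoundaryFixture] = []

    def add(name, position, bundle, canvig=None, auto=None):
        fx.append(
            BoundaryFixture(
                name=name,
                variant=_fixture_variant(name, position),
                bundle=bundle,
                expected_canvig=canvig,
                expected_auto=auto,
            )
        )

    blocked = 0.5  # splice score blocking BP1 in the gene-specific engine

    # REVEL strict thresholds (position with splice guard blocking BP1)
    add("revel_0.39", 1200, AnnotationBundle(revel=0.39, splice_score=blocked),
        canvig=FiveTier.LBV)
    add("revel_0.40", 1200, AnnotationBundle(revel=0.40, splice_score=blocked),
        canvig=FiveTier.VUS)
    add("revel_0.70", 1200, AnnotationBundle(revel=0.70, splice_score=blocked),
        canvig=FiveTier.VUS)
    add("revel_0.71", 1200, AnnotationBundle(revel=0.71, splice_score=blocked),
        canvig=FiveTier.VUS)

    # splice guard for BP1 outside the functional domains
    add("splice_0.19", 1200, AnnotationBundle(splice_score=0.19),
        canvig=FiveTier.LBV)
    add("splice_0.20", 1200, AnnotationBundle(splice_score=0.20),
        canvig=FiveTier.VUS)

    # case-control odds ratio, inclusive threshold; paired with a strong
    # abnormal assay so the boundary is visible at category level
    add("or_9.9", 1200,
        AnnotationBundle(case_control_or=9.9, functional_result="abnormal",
                         assay_strength=Strength.STRONG, splice_score=blocked),
        canvig=FiveTier.VUS)
    add("or_10", 1200,
        AnnotationBundle(case_control_or=10.0, functional_result="abnormal",
                         assay_strength=Strength.STRONG, splice_score=blocked),
        canvig=FiveTier.LPV)

    # allele counts one allele either side of the frequency tolerances
    an = 100_000  # tolerated counts: 117 (stand-alone), 15 (strong)
    add("ac_at_ba1_tol", 1200,
        AnnotationBundle(af=117 / an, allele_count=117, allele_number=an,
                         splice_score=blocked),
        canvig=FiveTier.LBV)  # BS1 strong only
    add("ac_above_ba1_tol", 1200,
        AnnotationBundle(af=118 / an, allele_count=118, allele_number=an,
                         splice_score=blocked),
        canvig=FiveTier.BV, auto=FiveTier.BV)  # stand-alone
    add("ac_at_bs1_tol", 1200,
        AnnotationBundle(af=15 / an, allele_count=15, allele_number=an,
                         splice_score=blocked),
        canvig=FiveTier.VUS)  # PM2 supporting
    add("ac_above_bs1_tol", 1200,
        AnnotationBundle(af=16 / an, allele_count=16, allele_number=an,
                         splice_score=blocked),
        canvig=FiveTier.LBV)  # BS1 strong

    # point totals at every category boundary (gene-specific engine)
    add("total_10", 50,
        AnnotationBundle(functional_result="abnormal", assay_strength=Strength.STRONG,
                         case_control_or=12.0, revel=0.80),
        canvig=FiveTier.PV)  # PS3+4, PS4+4, PM1+1, PP3+1
    add("total_9", 1200,
        AnnotationBundle(functional_result="abnormal", assay_strength=Strength.STRONG,
                         case_control_or=12.0, revel=0.80, splice_score=blocked),
        canvig=FiveTier.LPV)  # PS3+4, PS4+4, PP3+1
    add("total_6", 1200,
        AnnotationBundle(functional_result="abnormal", assay_strength=Strength.MODERATE,
                         case_control_or=12.0, splice_score=blocked),
        canvig=FiveTier.LPV)  # PS3+2, PS4+4
    add("total_5", 1200,
        AnnotationBundle(case_control_or=12.0, revel=0.80, splice_score=blocked),
        canvig=FiveTier.VUS)  # PS4+4, PP3+1
    add("total_0", 1200, AnnotationBundle(splice_score=blocked),
        canvig=FiveTier.VUS)  # no evidence at all
    add("empty_auto", 50, AnnotationBundle(),
        canvig=FiveTier.VUS, auto=FiveTier.VUS)  # in-domain: PM1+1 vs nothing
    add("total_-1", 1200,
        AnnotationBundle(revel=0.30, splice_score=blocked),
        canvig=FiveTier.LBV)  # BP4-1
    add("total_-5", 1200,
        AnnotationBundle(functional_result="normal", assay_strength=Strength.STRONG,
                         revel=0.30, splice_score=blocked),
        canvig=FiveTier.LBV)  # BS3-4, BP4-1
    # the -6 divergence: same bundle totals -6 under both engines
    add("total_-6", 1200,
        AnnotationBundle(functional_result="normal", assay_strength=Strength.STRONG,
                         revel=0.30, metarnn=0.02, repeat_region=True),
        canvig=FiveTier.BV,   # BS3-4, BP4-1, BP1-1
        auto=FiveTier.LBV)    # BP4 strong -4, BP1 ext -1, BP3 -1
    add("total_-7_canvig", 1200,
        AnnotationBundle(functional_result="normal", assay_strength=Strength.STRONG,
                         revel=0.30, multifactorial_lr=0.40),
        canvig=FiveTier.BV)  # BS3-4, BP4-1, BP1-1, BP6-1
    add("total_-7_auto", 50,
        AnnotationBundle(metarnn=0.12, repeat_region=True,
                         allele_count=16, allele_number=100_000, af=16 / 100_000),
        auto=FiveTier.BV)  # BP4 mod -2, BP3 -1, BS1 -4 (in-domain: no BP1)
    return fx
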