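"""Gene-specific CanVIG-UK points engine for BRCA1 missense variants.

Implements the BRCA1/BRCA2 gene-specific refinement of the ACMG/AMP
criteria: population-frequency evidence against maximum-tolerated allele
counts (BA1/BS1/PM2), functional-assay evidence (PS3/BS3, including
splice-effect assays), same-residue precedent (PM5 modulated by REVEL),
multifactorial likelihood ratios (PP5/BP6), REVEL in-silico thresholds
(PP3/BP4), functional-domain location (PM1/BP1 with a splice guard),
case-control enrichment (PS4) and identical-amino-acid precedent (PS1).

Evidence points are summed and mapped to the five tiers through the
gene-specific threshold table (PV >= 10, LPV 6..9, VUS 0..5, LBV -5..-1,
BV <= -6), with two combination overrides:

* PM2 exclusion — a supporting PM2 is dropped from the total when it is
  the only pathogenic-direction element and the rest of the evidence is
  already in benign territory, so absence from gnomAD alone cannot dilute
  a benign call.
* VUS override — a benign-territory total is demoted to VUS when two or
  more pathogenic-direction elements were applied, keeping genuinely mixed
  evidence in the uncertain tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    AnnotationBundle,
    ClassificationResult,
    Consequence,
    Direction,
    EvidenceAssignment,
    EvidenceCode,
    FiveTier,
    Override,
    Strength,
    VariantRecord,
)
from .popfreq import FrequencyThresholds, max_tolerated_allele_count


@dataclass(frozen=True)
class CategoryThresholds:
    """Map a signed point total to a five-tier category.

    ``lbv_min`` is the most negative total still called likely benign;
    anything below it is benign.  The two engines differ only here:
    the gene-specific table uses lbv_min = -5 (BV <= -6), the automated
    table lbv_min = -6 (BV <= -7).
    """

    pv_min: int = 10
    lpv_min: int = 6
    vus_min: int = 0
    lbv_min: int = -5

    def __post_init__(self) -> None:
        if not (self.pv_min > self.lpv_min > self.vus_min > self.lbv_min):
            raise ValueError("category thresholds must be strictly ordered")

    def categorize(self, total: int) -> FiveTier:
        if total >= self.pv_min:
            return FiveTier.PV
        if total >= self.lpv_min:
            return FiveTier.LPV
        if total >= self.vus_min:
            return FiveTier.VUS
        if total >= self.lbv_min:
            return FiveTier.LBV
        return FiveTier.BV


@dataclass(frozen=True)
class DomainRegion:
    """A closed, 1-based amino-acid interval of a functional protein domain."""

    name: str
    start_aa: int
    end_aa: int
    critical_residues: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError(f"bad domain interval {self.name}: {self.start_aa}-{self.end_aa}")

    def __contains__(self, position: int) -> bool:
        return self.start_aa <= position <= self.end_aa


#: BRCA1 functional domains where missense changes are most often damaging.
BRCA1_DOMAINS: tuple[DomainRegion, ...] = (
    DomainRegion("RING", 1, 101),
    DomainRegion("COILED-COIL", 1391, 1424),
    DomainRegion("BRCT", 1650, 1863),
)


@dataclass(frozen=True)
class LrBins:
    """Monotone mapping from a multifactorial likelihood ratio to strength.

    Pathogenic cut-points follow the Bayesian points calibration
    (supporting ~2.08, moderate ~4.33, strong ~18.7, very strong ~350);
    benign strengths use the reciprocal cut-points and cap at strong.
    A ratio in the neutral band triggers nothing.
    """

    pathogenic: tuple[tuple[float, Strength], ...] = (
        (350.0, Strength.VERY_STRONG),
        (18.7, Strength.STRONG),
        (4.33, Strength.MODERATE),
        (2.08, Strength.SUPPORTING),
    )
    benign: tuple[tuple[float, Strength], ...] = (
        (1 / 18.7, Strength.STRONG),
        (1 / 4.33, Strength.MODERATE),
        (1 / 2.08, Strength.SUPPORTING),
    )

    def __post_init__(self) -> None:
        path = [t for t, _ in self.pathogenic]
        ben = [t for t, _ in self.benign]
        if path != sorted(path, reverse=True) or ben != sorted(ben):
            raise ValueError("likelihood-ratio bins must be monotone")

    def lookup(self, lr: float) -> tuple[Direction, Strength] | None:
        for threshold, strength in self.pathogenic:
            if lr >= threshold:
                return Direction.PATHOGENIC, strength
        for threshold, strength in self.benign:
            if lr <= threshold:
                return Direction.BENIGN, strength
        return None


@dataclass(frozen=True)
class CanvigConfig:
    """Tunable thresholds of the gene-specific engine; defaults are the published BRCA1 values."""

    frequency: FrequencyThresholds = field(default_factory=FrequencyThresholds)
    revel_pp3: float = 0.7
    revel_bp4: float = 0.4
    splice_bp1_max: float = 0.2
    ps4_or_min: float = 10.0
    ps4_strength: Strength = Strength.STRONG
    pm2_absent_strength: Strength = Strength.SUPPORTING
    bp1_when_splice_missing: bool = True
    domains: tuple[DomainRegion, ...] = BRCA1_DOMAINS
    lr_bins: LrBins = field(default_factory=LrBins)
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)

    def __post_init__(self) -> None:
        spans = sorted((d.start_aa, d.end_aa) for d in self.domains)
        for (_, end_prev), (start, _) in zip(spans, spans[1:]):
            if start <= end_prev:
                raise ValueError("domain intervals must not overlap")


DEFAULT_CONFIG = CanvigConfig()


def assess_population(
    bundle: AnnotationBundle, cfg: CanvigConfig = DEFAULT_CONFIG
) -> list[EvidenceAssignment]:
    """BA1 / BS1 / PM2 from observed allele counts.

    At most one of the three is emitted.  With counts available, the count
    is tested against the BA1 then BS1 tolerated counts; a count that
    exceeds neither (including zero, i.e. absence) is extremely low and
    yields PM2.  With only a point-estimate frequency available, the
    frequency itself is compared against the thresholds.  With no
    population data at all there is insufficient information and no
    evidence is emitted.
    """
    freq = cfg.frequency
    ac, an = bundle.allele_count, bundle.allele_number
    if ac is not None and an is not None:
        if ac > max_tolerated_allele_count(freq.ba1_af, an, freq.confidence):
            return [EvidenceAssignment.make(EvidenceCode.BA1, Strength.STANDALONE)]
        if ac > max_tolerated_allele_count(freq.bs1_af, an, freq.confidence):
            return [EvidenceAssignment.make(EvidenceCode.BS1, Strength.STRONG)]
        strength = cfg.pm2_absent_strength if ac == 0 else Strength.SUPPORTING
        return [EvidenceAssignment.make(EvidenceCode.PM2, strength)]
    if bundle.af is not None:
        # point-estimate fallback when counts are unavailable
        if bundle.af > freq.ba1_af:
            return [EvidenceAssignment.make(EvidenceCode.BA1, Strength.STANDALONE)]
        if bundle.af > freq.bs1_af:
            return [EvidenceAssignment.make(EvidenceCode.BS1, Strength.STRONG)]
        strength = cfg.pm2_absent_strength if bundle.af == 0 else Strength.SUPPORTING
        return [EvidenceAssignment.make(EvidenceCode.PM2, strength)]
    return []


def assess_functional(
    bundle: AnnotationBundle, cfg: CanvigConfig = DEFAULT_CONFIG
) -> list[EvidenceAssignment]:
    """PS3 / BS3 from well-established functional assays.

    The evidence grade comes with the assay (``assay_strength``); a result
    without a grade cannot be weighed and is rejected.  Intermediate
    results trigger nothing.  A splice-effect result is pathogenic
    functional evidence with the splice annotation retained.
    """
    result = bundle.functional_result
    if result is None or result == "intermediate":
        return []
    if bundle.assay_strength is None:
        raise ValueError(
            f"functional result {result!r} requires an assay strength grade"
        )
    if result == "abnormal":
        return [EvidenceAssignment.make(EvidenceCode.PS3, bundle.assay_strength)]
    if result == "splice_effect":
        return [
            EvidenceAssignment.make(
                EvidenceCode.PS3, bundle.assay_strength, note="splice effect"
            )
        ]
    if result == "normal":
        return [EvidenceAssignment.make(EvidenceCode.BS3, bundle.assay_strength)]
    raise ValueError(f"unknown functional result {result!r}")


def assess_same_residue(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    cfg: CanvigConfig = DEFAULT_CONFIG,
    max_strength: Strength = Strength.MODERATE,
) -> list[EvidenceAssignment]:
    """PM5 from a previously classified missense change at the same residue.

    Moderate when the query's REVEL is equivalent or more deleterious than
    the reference's and the reference is an established call; supporting
    when the reference is an LPV with limited reports or the query scores
    less deleterious.  The strongest applicable grade over all references
    is emitted, at most once.  ``max_strength`` lets the automated engine
    escalate to strong for a PV reference (its observed behaviour); the
    gene-specific engine caps at moderate.
    """
    if not bundle.same_residue_refs:
        return []
    order = [Strength.SUPPORTING, Strength.MODERATE, Strength.STRONG]
    best: Strength | None = None
    for ref in bundle.same_residue_refs:
        if (
            bundle.revel is not None
            and ref.revel is not None
            and bundle.revel >= ref.revel
            and not (ref.classification is FiveTier.LPV and ref.limited_reports)
        ):
            strength = Strength.MODERATE
            if (
                max_strength is Strength.STRONG
                and ref.classification is FiveTier.PV
            ):
                strength = Strength.STRONG
        else:
            strength = Strength.SUPPORTING
        if best is None or order.index(strength) > order.index(best):
            best = strength
    cap = order.index(max_strength)
    if order.index(best) > cap:
        best = max_strength
    return [EvidenceAssignment.make(EvidenceCode.PM5, best)]


def assess_multifactorial(
    bundle: AnnotationBundle, cfg: CanvigConfig = DEFAULT_CONFIG
) -> list[EvidenceAssignment]:
    """PP5 / BP6 from a published multifactorial likelihood ratio."""
    lr = bundle.multifactorial_lr
    if lr is None:
        return []
    if not lr > 0:
        raise ValueError(f"multifactorial likelihood ratio must be > 0, got {lr}")
    hit = cfg.lr_bins.lookup(lr)
    if hit is None:
        return []
    direction, strength = hit
    code = EvidenceCode.PP5 if direction is Direction.PATHOGENIC else EvidenceCode.BP6
    return [EvidenceAssignment.make(code, strength)]


def assess_insilico(
    bundle: AnnotationBundle, cfg: CanvigConfig = DEFAULT_CONFIG
) -> list[EvidenceAssignment]:
    """PP3 / BP4 from REVEL with strict thresholds; the middle band is silent."""
    if bundle.revel is None:
        return []
    if bundle.revel > cfg.revel_pp3:
        return [EvidenceAssignment.make(EvidenceCode.PP3, Strength.SUPPORTING)]
    if bundle.revel < cfg.revel_bp4:
        return [EvidenceAssignment.make(EvidenceCode.BP4, Strength.SUPPORTING)]
    return []


def domain_of(position: int, domains: tuple[DomainRegion, ...]) -> DomainRegion | None:
    for dom in domains:
        if position in dom:
            return dom
    return None


def assess_location(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    cfg: CanvigConfig = DEFAULT_CONFIG,
) -> list[EvidenceAssignment]:
    """PM1 inside a functional domain, BP1 outside when splicing is excluded.

    PM1 is moderate at configured critical residues, supporting elsewhere
    in the domain.  BP1 applies only when the predicted splice impact is
    below the guard threshold; a missing splice prediction counts as no
    predicted effect by default (config-switchable).
    """
    dom = domain_of(variant.protein_position, cfg.domains)
    if dom is not None:
        strength = (
            Strength.MODERATE
            if variant.protein_position in dom.critical_residues
            else Strength.SUPPORTING
        )
        return [EvidenceAssignment.make(EvidenceCode.PM1, strength, note=dom.name)]
    if bundle.splice_score is None:
        if cfg.bp1_when_splice_missing:
            return [EvidenceAssignment.make(EvidenceCode.BP1, Strength.SUPPORTING)]
        return []
    if bundle.splice_score < cfg.splice_bp1_max:
        return [EvidenceAssignment.make(EvidenceCode.BP1, Strength.SUPPORTING)]
    return []


def assess_case_control(
    bundle: AnnotationBundle, cfg: CanvigConfig = DEFAULT_CONFIG
) -> list[EvidenceAssignment]:
    """PS4 when the case-control odds ratio reaches the enrichment threshold (inclusive)."""
    odds = bundle.case_control_or
    if odds is None:
        return []
    if not odds > 0:
        raise ValueError(f"case-control odds ratio must be > 0, got {odds}")
    if odds >= cfg.ps4_or_min:
        return [EvidenceAssignment.make(EvidenceCode.PS4, cfg.ps4_strength)]
    return []


def assess_same_aa_change(
    bundle: AnnotationBundle, cfg: CanvigConfig = DEFAULT_CONFIG
) -> list[EvidenceAssignment]:
    """PS1 (strong) when an identical amino-acid change has an established pathogenic call."""
    if bundle.same_aa_change_pathogenic:
        return [EvidenceAssignment.make(EvidenceCode.PS1, Strength.STRONG)]
    return []


def _canonical(evidence: list[EvidenceAssignment]) -> tuple[EvidenceAssignment, ...]:
    """Sort by code so combination is order-independent; reject duplicates."""
    ordered = tuple(sorted(evidence, key=lambda e: e.code.value))
    codes = [e.code for e in ordered]
    if len(set(codes)) != len(codes):
        dupes = sorted({c.value for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate evidence codes: {', '.join(dupes)}")
    return ordered


def combine_canvig(
    evidence: list[EvidenceAssignment], cfg: CanvigConfig = DEFAULT_CONFIG
) -> ClassificationResult:
    """Sum evidence points and map to a category with the gene-specific overrides.

    Order of application: BA1 stand-alone first (benign regardless of the
    total), then the PM2 exclusion on the total, then the threshold table,
    then the VUS override on benign-territory calls carrying two or more
    pathogenic-direction elements.
    """
    ordered = _canonical(list(evidence))
    total = sum(e.points for e in ordered)
    if any(e.code is EvidenceCode.BA1 for e in ordered):
        return ClassificationResult(
            FiveTier.BV, total, ordered, (Override.BA1_STANDALONE,)
        )
    overrides: list[Override] = []
    pathogenic = [e for e in ordered if e.direction is Direction.PATHOGENIC]
    pm2 = next((e for e in ordered if e.code is EvidenceCode.PM2), None)
    if pm2 is not None and pathogenic == [pm2]:
        remainder = total - pm2.points
        if cfg.thresholds.categorize(remainder) in (FiveTier.LBV, FiveTier.BV):
            total = remainder
            overrides.append(Override.PM2_EXCLUDED)
    category = cfg.thresholds.categorize(total)
    if category in (FiveTier.LBV, FiveTier.BV) and len(pathogenic) >= 2:
        category = FiveTier.VUS
        overrides.append(Override.VUS_OVERRIDE)
    return ClassificationResult(category, total, ordered, tuple(overrides))


def classify_variant_canvig(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    cfg: CanvigConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """Run every gene-specific assessment and combine; deterministic for fixed inputs."""
    if variant.consequence is not Consequence.MISSENSE:
        raise ValueError(
            f"{variant.variant_id}: engine classifies missense variants only, "
            f"got {variant.consequence.value}"
        )
    evidence: list[EvidenceAssignment] = []
    try:
        evidence += assess_population(bundle, cfg)
        evidence += assess_functional(bundle, cfg)
        evidence += assess_same_residue(variant, bundle, cfg)
        evidence += assess_multifactorial(bundle, cfg)
        evidence += assess_insilico(bundle, cfg)
        evidence += assess_location(variant, bundle, cfg)
        evidence += assess_case_control(bundle, cfg)
        evidence += assess_same_aa_change(bundle, cfg)
    except ValueError as exc:
        raise ValueError(f"{variant.variant_id}: {exc}") from exc
    return combine_canvig(evidence, cfg)
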