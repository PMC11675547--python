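"""Automated generic ACMG points engine (VarSome-style emulation).

Shares the evidence-combination machinery with the gene-specific engine
but reproduces the behaviours characteristic of fully automated
interpretation: MetaRNN-calibrated computational evidence graded from
supporting to strong, BP3 applied to missense variants in repeat regions,
BP1 extended to any missense outside the functional domains regardless of
splice predictions, PM5 escalated to strong for a pathogenic same-residue
reference, and no curator overrides — the point total maps straight
through this engine's threshold table (PV >= 10, LPV 6..9, VUS 0..5,
LBV -6..-1, BV <= -7).  Functional-assay evidence is unavailable by
default, reflecting that automated classification typically lacks curated
assay calls; a toggle enables it.

Each toggle is an explicit emulation switch for an observed behaviour of
the automated tool, not a claim about its proprietary internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .canvig import (
    CategoryThresholds,
    DomainRegion,
    BRCA1_DOMAINS,
    assess_functional,
    assess_population,
    assess_same_aa_change,
    assess_same_residue,
    domain_of,
    _canonical,
)
from .canvig import CanvigConfig as _SharedAssessorConfig
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
from .popfreq import FrequencyThresholds


@dataclass(frozen=True)
class ScoreBins:
    """Monotone calibration of an in-silico score to (direction, strength).

    ``pathogenic`` thresholds are descending lower bounds (score >= t),
    ``benign`` ascending upper bounds (score <= t); the gap between the
    weakest bounds is a neutral band that triggers nothing.
    """

    pathogenic: tuple[tuple[float, Strength], ...] = (
        (0.94, Strength.STRONG),
        (0.85, Strength.MODERATE),
        (0.75, Strength.SUPPORTING),
    )
    benign: tuple[tuple[float, Strength], ...] = (
        (0.05, Strength.STRONG),
        (0.15, Strength.MODERATE),
        (0.30, Strength.SUPPORTING),
    )

    def __post_init__(self) -> None:
        path = [t for t, _ in self.pathogenic]
        ben = [t for t, _ in self.benign]
        if path != sorted(path, reverse=True) or ben != sorted(ben):
            raise ValueError("score bins must be monotone")
        if ben and path and max(ben) >= min(path):
            raise ValueError("benign and pathogenic score bins overlap")

    def lookup(self, score: float) -> tuple[Direction, Strength] | None:
        for threshold, strength in self.pathogenic:
            if score >= threshold:
                return Direction.PATHOGENIC, strength
        for threshold, strength in self.benign:
            if score <= threshold:
                return Direction.BENIGN, strength
        return None


@dataclass(frozen=True)
class AutoEngineConfig:
    """Thresholds and emulation toggles of the automated engine."""

    frequency: FrequencyThresholds = field(default_factory=FrequencyThresholds)
    thresholds: CategoryThresholds = field(
        default_factory=lambda: CategoryThresholds(lbv_min=-6)
    )
    metarnn_bins: ScoreBins = field(default_factory=ScoreBins)
    domains: tuple[DomainRegion, ...] = BRCA1_DOMAINS
    apply_bp3_missense: bool = True
    apply_bp1_extended: bool = True
    allow_pm5_strong: bool = True
    graded_bp4: bool = True
    use_functional: bool = False


DEFAULT_AUTO_CONFIG = AutoEngineConfig()


def _shared_cfg(cfg: AutoEngineConfig) -> _SharedAssessorConfig:
    """Adapter handing this engine's thresholds to the shared assessors."""
    return _SharedAssessorConfig(frequency=cfg.frequency, domains=cfg.domains)


def assess_computational_auto(
    bundle: AnnotationBundle, cfg: AutoEngineConfig = DEFAULT_AUTO_CONFIG
) -> list[EvidenceAssignment]:
    """PP3 / BP4 from MetaRNN through the calibration bins.

    Benign strength is capped at supporting when graded BP4 is toggled
    off (the behaviour that distinguishes graded automated engines from
    guidance applying only supporting strength).
    """
    score = bundle.metarnn
    if score is None:
        return []
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"metarnn score must lie in [0, 1], got {score}")
    hit = cfg.metarnn_bins.lookup(score)
    if hit is None:
        return []
    direction, strength = hit
    if direction is Direction.PATHOGENIC:
        return [EvidenceAssignment.make(EvidenceCode.PP3, strength)]
    if not cfg.graded_bp4:
        strength = Strength.SUPPORTING
    return [EvidenceAssignment.make(EvidenceCode.BP4, strength)]


def assess_region_auto(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    cfg: AutoEngineConfig = DEFAULT_AUTO_CONFIG,
) -> list[EvidenceAssignment]:
    """BP3 and extended BP1 per the emulation toggles.

    BP3 (repeat region without known function) fires for missense variants
    flagged as lying in such a region.  Extended BP1 fires for any
    missense outside the functional domains, without the splice guard the
    gene-specific engine applies.
    """
    out: list[EvidenceAssignment] = []
    if cfg.apply_bp3_missense and bundle.repeat_region:
        out.append(EvidenceAssignment.make(EvidenceCode.BP3, Strength.SUPPORTING))
    if cfg.apply_bp1_extended and domain_of(variant.protein_position, cfg.domains) is None:
        out.append(EvidenceAssignment.make(EvidenceCode.BP1, Strength.SUPPORTING))
    return out


def combine_auto(
    evidence: list[EvidenceAssignment], cfg: AutoEngineConfig = DEFAULT_AUTO_CONFIG
) -> ClassificationResult:
    """Sum points and map through this engine's thresholds; BA1 stays stand-alone.

    No curator overrides: neither the PM2 exclusion nor the VUS demotion
    of the gene-specific engine applies here.
    """
    ordered = _canonical(list(evidence))
    total = sum(e.points for e in ordered)
    if any(e.code is EvidenceCode.BA1 for e in ordered):
        return ClassificationResult(
            FiveTier.BV, total, ordered, (Override.BA1_STANDALONE,)
        )
    return ClassificationResult(cfg.thresholds.categorize(total), total, ordered)


def classify_variant_auto(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    cfg: AutoEngineConfig = DEFAULT_AUTO_CONFIG,
) -> ClassificationResult:
    """Assemble automated evidence and combine; deterministic for fixed inputs."""
    if variant.consequence is not Consequence.MISSENSE:
        raise ValueError(
            f"{variant.variant_id}: engine classifies missense variants only, "
            f"got {variant.consequence.value}"
        )
    shared = _shared_cfg(cfg)
    evidence: list[EvidenceAssignment] = []
    try:
        evidence += assess_population(bundle, shared)
        if cfg.use_functional:
            evidence += assess_functional(bundle, shared)
        evidence += assess_same_residue(
            variant,
            bundle,
            shared,
            max_strength=Strength.STRONG if cfg.allow_pm5_strong else Strength.MODERATE,
        )
        evidence += assess_computational_auto(bundle, cfg)
        evidence += assess_region_auto(variant, bundle, cfg)
        evidence += assess_same_aa_change(bundle, shared)
    except ValueError as exc:
        raise ValueError(f"{variant.variant_id}: {exc}") from exc
    return combine_auto(evidence, cfg)
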