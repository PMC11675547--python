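"""Automated engine: calibration bins, emulation toggles, threshold table
divergence at -6, and agreement with the gene-specific combiner."""

import itertools

import pytest

from varpoints.autoengine import (
    AutoEngineConfig,
    ScoreBins,
    assess_computational_auto,
    assess_region_auto,
    classify_variant_auto,
    combine_auto,
)
from varpoints.canvig import combine_canvig
from varpoints.model import (
    AnnotationBundle,
    EvidenceAssignment,
    EvidenceCode,
    FiveTier,
    Override,
    SameResidueRef,
    Strength,
    VariantRecord,
)

E = EvidenceAssignment.make


def variant_at(position: int) -> VariantRecord:
    return VariantRecord(
        variant_id=f"v{position}", gene="BRCA1", hgvs_c="c.1A>G",
        hgvs_p=f"p.X{position}Y", protein_position=position,
    )


# --- computational bins -----------------------------------------------------

@pytest.mark.parametrize(
    "score, code, strength",
    [
        (1.0, EvidenceCode.PP3, Strength.STRONG),
        (0.90, EvidenceCode.PP3, Strength.MODERATE),
        (0.76, EvidenceCode.PP3, Strength.SUPPORTING),
        (0.20, EvidenceCode.BP4, Strength.SUPPORTING),
        (0.10, EvidenceCode.BP4, Strength.MODERATE),
        (0.025, EvidenceCode.BP4, Strength.STRONG),
    ],
)
def test_metarnn_bin_lookup(score, code, strength):
    out = assess_computational_auto(AnnotationBundle(metarnn=score))
    assert [a.code for a in out] == [code]
    assert out[0].strength is strength


def test_neutral_band_and_absence_trigger_nothing():
    assert assess_computational_auto(AnnotationBundle(metarnn=0.5)) == []
    assert assess_computational_auto(AnnotationBundle()) == []


def test_graded_bp4_toggle_caps_benign_strength():
    cfg = AutoEngineConfig(graded_bp4=False)
    out = assess_computational_auto(AnnotationBundle(metarnn=0.02), cfg)
    assert out[0].strength is Strength.SUPPORTING


def test_score_bins_reject_non_monotone_or_overlapping():
    with pytest.raises(ValueError):
        ScoreBins(pathogenic=((0.8, Strength.SUPPORTING), (0.9, Strength.STRONG)))
    with pytest.raises(ValueError):
        ScoreBins(benign=((0.8, Strength.STRONG),))  # overlaps pathogenic 0.75


# --- region toggles ---------------------------------------------------------

def test_bp3_applies_to_flagged_repeat_missense():
    out = assess_region_auto(variant_at(50), AnnotationBundle(repeat_region=True))
    assert [a.code for a in out] == [EvidenceCode.BP3]
    cfg = AutoEngineConfig(apply_bp3_missense=False)
    assert assess_region_auto(variant_at(50), AnnotationBundle(repeat_region=True), cfg) == []


def test_extended_bp1_ignores_splice_prediction():
    out = assess_region_auto(
        variant_at(1200), AnnotationBundle(splice_score=0.9)
    )
    assert [a.code for a in out] == [EvidenceCode.BP1]
    cfg = AutoEngineConfig(apply_bp1_extended=False)
    assert assess_region_auto(variant_at(1200), AnnotationBundle(), cfg) == []


# --- PM5 escalation ---------------------------------------------------------

def test_pm5_escalates_to_strong_for_pathogenic_reference():
    bundle = AnnotationBundle(
        revel=0.9,
        same_residue_refs=(
            SameResidueRef(hgvs_p="p.ref", classification=FiveTier.PV, revel=0.8),
        ),
    )
    result = classify_variant_auto(variant_at(50), bundle)
    pm5 = next(e for e in result.evidence if e.code is EvidenceCode.PM5)
    assert pm5.strength is Strength.STRONG
    capped = classify_variant_auto(
        variant_at(50), bundle, AutoEngineConfig(allow_pm5_strong=False)
    )
    pm5 = next(e for e in capped.evidence if e.code is EvidenceCode.PM5)
    assert pm5.strength is Strength.MODERATE


# --- functional availability ------------------------------------------------

def test_functional_evidence_defaults_off_and_can_be_enabled():
    bundle = AnnotationBundle(
        functional_result="abnormal", assay_strength=Strength.STRONG, splice_score=0.5
    )
    off = classify_variant_auto(variant_at(50), bundle)
    assert EvidenceCode.PS3 not in [e.code for e in off.evidence]
    on = classify_variant_auto(
        variant_at(50), bundle, AutoEngineConfig(use_functional=True)
    )
    assert EvidenceCode.PS3 in [e.code for e in on.evidence]


# --- combination and thresholds ---------------------------------------------

def test_total_minus_six_diverges_between_engines():
    evidence = [
        E(EvidenceCode.BS3, Strength.STRONG),
        E(EvidenceCode.BP4, Strength.SUPPORTING),
        E(EvidenceCode.BP1, Strength.SUPPORTING),
    ]
    assert combine_canvig(evidence).category is FiveTier.BV
    assert combine_auto(evidence).category is FiveTier.LBV
    evidence.append(E(EvidenceCode.BP3, Strength.SUPPORTING))
    assert combine_auto(evidence).category is FiveTier.BV  # -7


def test_combine_auto_has_no_curator_overrides():
    result = combine_auto(
        [E(EvidenceCode.PM2, Strength.SUPPORTING), E(EvidenceCode.BP4, Strength.SUPPORTING)]
    )
    assert result.total_points == 0 and result.category is FiveTier.VUS
    assert result.overrides_applied == ()
    mixed = combine_auto(
        [E(EvidenceCode.PP3, Strength.SUPPORTING), E(EvidenceCode.PM1, Strength.SUPPORTING),
         E(EvidenceCode.BS3, Strength.STRONG)]
    )
    assert mixed.category is FiveTier.LBV  # -2, no demotion to VUS


def test_ba1_remains_standalone_in_auto_engine():
    result = combine_auto([E(EvidenceCode.BA1, Strength.STANDALONE)])
    assert result.category is FiveTier.BV
    assert result.overrides_applied == (Override.BA1_STANDALONE,)


def categorize_auto_literal(total: int) -> FiveTier:
    if total >= 10:
        return FiveTier.PV
    if 6 <= total <= 9:
        return FiveTier.LPV
    if 0 <= total <= 5:
        return FiveTier.VUS
    if -6 <= total <= -1:
        return FiveTier.LBV
    return FiveTier.BV


POOL = [
    E(EvidenceCode.PM2, Strength.SUPPORTING), E(EvidenceCode.PP3, Strength.STRONG),
    E(EvidenceCode.PM5, Strength.STRONG), E(EvidenceCode.BP3, Strength.SUPPORTING),
    E(EvidenceCode.BP4, Strength.STRONG), E(EvidenceCode.BS1, Strength.STRONG),
]


def test_combine_auto_matches_subset_enumeration():
    for r in range(len(POOL) + 1):
        for subset in itertools.combinations(POOL, r):
            result = combine_auto(list(subset))
            total = sum(e.points for e in subset)
            assert result.total_points == total
            assert result.category is categorize_auto_literal(total), subset


def test_engines_agree_except_at_minus_six():
    """Identical evidence: totals always equal; categories split only at -6."""
    for r in range(len(POOL) + 1):
        for subset in itertools.combinations(POOL, r):
            canvig = combine_canvig(list(subset))
            auto = combine_auto(list(subset))
            if canvig.overrides_applied:
                continue  # curator overrides are gene-specific by design
            assert canvig.total_points == auto.total_points
            if canvig.total_points == -6:
                assert (canvig.category, auto.category) == (FiveTier.BV, FiveTier.LBV)
            else:
                assert canvig.category is auto.category
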