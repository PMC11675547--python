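"""Gene-specific engine: per-criterion assessments, combination overrides,
and equivalence with a literal brute-force combiner over evidence subsets."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from varpoints.canvig import (
    CanvigConfig,
    CategoryThresholds,
    assess_case_control,
    assess_functional,
    assess_insilico,
    assess_location,
    assess_multifactorial,
    assess_population,
    assess_same_residue,
    classify_variant_canvig,
    combine_canvig,
)
from varpoints.model import (
    AnnotationBundle,
    Consequence,
    EvidenceAssignment,
    EvidenceCode,
    FiveTier,
    Override,
    SameResidueRef,
    Strength,
    VariantRecord,
)

E = EvidenceAssignment.make
CFG = CanvigConfig()


def variant_at(position: int) -> VariantRecord:
    return VariantRecord(
        variant_id=f"v{position}", gene="BRCA1", hgvs_c="c.1A>G",
        hgvs_p=f"p.X{position}Y", protein_position=position,
    )


# --- population -------------------------------------------------------------

def codes(assignments):
    return [a.code for a in assignments]


def test_population_common_variant_is_standalone_benign():
    bundle = AnnotationBundle(af=0.002, allele_count=200, allele_number=100_000)
    assert codes(assess_population(bundle)) == [EvidenceCode.BA1]


def test_population_absence_gives_pm2_supporting():
    out = assess_population(AnnotationBundle(af=0.0, allele_count=0, allele_number=50_000))
    assert codes(out) == [EvidenceCode.PM2]
    assert out[0].strength is Strength.SUPPORTING


def test_population_count_at_tolerance_is_not_strong_benign():
    # tolerated count for the strong-benign threshold at AN=100000 is 15
    bundle = AnnotationBundle(af=15 / 100_000, allele_count=15, allele_number=100_000)
    assert codes(assess_population(bundle)) == [EvidenceCode.PM2]
    bundle = AnnotationBundle(af=16 / 100_000, allele_count=16, allele_number=100_000)
    assert codes(assess_population(bundle)) == [EvidenceCode.BS1]


def test_population_without_data_emits_nothing():
    assert assess_population(AnnotationBundle()) == []


def test_population_emits_at_most_one_code():
    for ac in (0, 10, 50, 500):
        out = assess_population(
            AnnotationBundle(af=ac / 100_000, allele_count=ac, allele_number=100_000)
        )
        assert len(out) == 1


# --- functional -------------------------------------------------------------

@pytest.mark.parametrize(
    "result, strength, code, points",
    [
        ("abnormal", Strength.STRONG, EvidenceCode.PS3, 4),
        ("abnormal", Strength.SUPPORTING, EvidenceCode.PS3, 1),
        ("normal", Strength.STRONG, EvidenceCode.BS3, -4),
        ("splice_effect", Strength.STRONG, EvidenceCode.PS3, 4),
    ],
)
def test_functional_assay_mapping(result, strength, code, points):
    out = assess_functional(
        AnnotationBundle(functional_result=result, assay_strength=strength)
    )
    assert codes(out) == [code]
    assert out[0].points == points


def test_splice_effect_retains_annotation():
    out = assess_functional(
        AnnotationBundle(functional_result="splice_effect", assay_strength=Strength.STRONG)
    )
    assert out[0].note == "splice effect"


def test_intermediate_or_absent_assay_triggers_nothing():
    assert assess_functional(AnnotationBundle(functional_result="intermediate")) == []
    assert assess_functional(AnnotationBundle()) == []


def test_assay_without_strength_is_rejected_naming_variant():
    bundle = AnnotationBundle(functional_result="abnormal")
    with pytest.raises(ValueError, match="assay strength"):
        assess_functional(bundle)
    with pytest.raises(ValueError, match="v1803"):
        classify_variant_canvig(variant_at(1803), bundle)


# --- same residue -----------------------------------------------------------

def ref(cls=FiveTier.PV, revel=0.80, limited=False):
    return SameResidueRef(
        hgvs_p="p.ref", classification=cls, revel=revel, limited_reports=limited
    )


def test_pm5_moderate_when_query_at_least_as_deleterious(missense_variant):
    out = assess_same_residue(
        missense_variant, AnnotationBundle(revel=0.85, same_residue_refs=(ref(),))
    )
    assert codes(out) == [EvidenceCode.PM5]
    assert out[0].strength is Strength.MODERATE and out[0].points == 2


def test_pm5_supporting_when_query_less_deleterious(missense_variant):
    out = assess_same_residue(
        missense_variant, AnnotationBundle(revel=0.60, same_residue_refs=(ref(),))
    )
    assert out[0].strength is Strength.SUPPORTING and out[0].points == 1


def test_pm5_supporting_for_limited_lpv_reference(missense_variant):
    out = assess_same_residue(
        missense_variant,
        AnnotationBundle(
            revel=0.95, same_residue_refs=(ref(FiveTier.LPV, 0.8, limited=True),)
        ),
    )
    assert out[0].strength is Strength.SUPPORTING


def test_pm5_absent_without_references(missense_variant):
    assert assess_same_residue(missense_variant, AnnotationBundle(revel=0.9)) == []


def test_pm5_emitted_once_at_strongest_grade(missense_variant):
    refs = (ref(FiveTier.LPV, 0.9, limited=True), ref(FiveTier.PV, 0.7))
    out = assess_same_residue(
        missense_variant, AnnotationBundle(revel=0.8, same_residue_refs=refs)
    )
    assert len(out) == 1 and out[0].strength is Strength.MODERATE


# --- multifactorial ---------------------------------------------------------

@pytest.mark.parametrize(
    "lr, code, strength",
    [
        (400.0, EvidenceCode.PP5, Strength.VERY_STRONG),
        (20.0, EvidenceCode.PP5, Strength.STRONG),
        (5.0, EvidenceCode.PP5, Strength.MODERATE),
        (2.1, EvidenceCode.PP5, Strength.SUPPORTING),
        (0.45, EvidenceCode.BP6, Strength.SUPPORTING),
        (0.2, EvidenceCode.BP6, Strength.MODERATE),
        (0.05, EvidenceCode.BP6, Strength.STRONG),
    ],
)
def test_likelihood_ratio_bins(lr, code, strength):
    out = assess_multifactorial(AnnotationBundle(multifactorial_lr=lr))
    assert codes(out) == [code] and out[0].strength is strength


def test_neutral_likelihood_ratio_triggers_nothing():
    assert assess_multifactorial(AnnotationBundle(multifactorial_lr=1.0)) == []
    assert assess_multifactorial(AnnotationBundle()) == []


def test_nonpositive_likelihood_ratio_rejected():
    with pytest.raises(ValueError):
        AnnotationBundle(multifactorial_lr=-2.0)


# --- in silico --------------------------------------------------------------

@pytest.mark.parametrize(
    "revel, expected",
    [
        (0.71, [EvidenceCode.PP3]),
        (0.39, [EvidenceCode.BP4]),
        (0.70, []),
        (0.40, []),
        (None, []),
    ],
)
def test_revel_thresholds_are_strict(revel, expected):
    assert codes(assess_insilico(AnnotationBundle(revel=revel))) == expected


# --- location ---------------------------------------------------------------

def test_domain_position_gets_pm1():
    out = assess_location(variant_at(50), AnnotationBundle())
    assert codes(out) == [EvidenceCode.PM1]
    assert out[0].strength is Strength.SUPPORTING and out[0].note == "RING"


def test_critical_residue_upgrades_pm1_to_moderate():
    from varpoints.canvig import DomainRegion

    cfg = CanvigConfig(
        domains=(DomainRegion("RING", 1, 101, critical_residues=frozenset({50})),)
    )
    out = assess_location(variant_at(50), AnnotationBundle(), cfg)
    assert out[0].strength is Strength.MODERATE


def test_outside_domain_with_low_splice_gets_bp1():
    out = assess_location(variant_at(1200), AnnotationBundle(splice_score=0.05))
    assert codes(out) == [EvidenceCode.BP1]


def test_splice_guard_blocks_bp1():
    assert assess_location(variant_at(1200), AnnotationBundle(splice_score=0.5)) == []


def test_missing_splice_score_default_allows_bp1_and_is_switchable():
    assert codes(assess_location(variant_at(1200), AnnotationBundle())) == [
        EvidenceCode.BP1
    ]
    cfg = CanvigConfig(bp1_when_splice_missing=False)
    assert assess_location(variant_at(1200), AnnotationBundle(), cfg) == []


# --- case-control -----------------------------------------------------------

@pytest.mark.parametrize("odds, hits", [(12.0, True), (10.0, True), (9.9, False)])
def test_odds_ratio_threshold_inclusive(odds, hits):
    out = assess_case_control(AnnotationBundle(case_control_or=odds))
    assert (codes(out) == [EvidenceCode.PS4]) is hits


# --- combination ------------------------------------------------------------

def test_combine_simple_sum_maps_to_category():
    result = combine_canvig(
        [E(EvidenceCode.PS3, Strength.STRONG), E(EvidenceCode.PM2, Strength.SUPPORTING),
         E(EvidenceCode.PP3, Strength.SUPPORTING)]
    )
    assert result.total_points == 6 and result.category is FiveTier.LPV
    assert result.overrides_applied == ()


def test_combine_pm2_exclusion():
    result = combine_canvig(
        [E(EvidenceCode.PM2, Strength.SUPPORTING), E(EvidenceCode.BP4, Strength.SUPPORTING)]
    )
    assert result.total_points == -1
    assert result.category is FiveTier.LBV
    assert Override.PM2_EXCLUDED in result.overrides_applied


def test_combine_vus_override_with_two_pathogenic_elements():
    result = combine_canvig(
        [E(EvidenceCode.PP3, Strength.SUPPORTING), E(EvidenceCode.PM1, Strength.SUPPORTING),
         E(EvidenceCode.BS3, Strength.STRONG)]
    )
    assert result.total_points == -2
    assert result.category is FiveTier.VUS
    assert Override.VUS_OVERRIDE in result.overrides_applied


def test_combine_ba1_standalone_forces_benign():
    result = combine_canvig(
        [E(EvidenceCode.BA1, Strength.STANDALONE), E(EvidenceCode.PP3, Strength.SUPPORTING)]
    )
    assert result.category is FiveTier.BV
    assert result.overrides_applied == (Override.BA1_STANDALONE,)


def test_combine_rejects_duplicate_codes():
    with pytest.raises(ValueError, match="PP3"):
        combine_canvig(
            [E(EvidenceCode.PP3, Strength.SUPPORTING), E(EvidenceCode.PP3, Strength.SUPPORTING)]
        )


def test_combine_is_order_independent():
    pool = [E(EvidenceCode.PS3, Strength.STRONG), E(EvidenceCode.BP4, Strength.SUPPORTING),
            E(EvidenceCode.PM2, Strength.SUPPORTING)]
    results = {
        (combine_canvig(list(perm)).category, combine_canvig(list(perm)).total_points)
        for perm in itertools.permutations(pool)
    }
    assert len(results) == 1


@pytest.mark.parametrize(
    "total, category",
    [(10, FiveTier.PV), (6, FiveTier.LPV), (0, FiveTier.VUS), (5, FiveTier.VUS),
     (-1, FiveTier.LBV), (-5, FiveTier.LBV), (-6, FiveTier.BV)],
)
def test_category_boundaries(total, category):
    assert CategoryThresholds().categorize(total) is category


# --- brute-force subset oracle ----------------------------------------------

def categorize_literal(total: int) -> FiveTier:
    """Threshold table written out literally, independent of the engine."""
    if total >= 10:
        return FiveTier.PV
    if 6 <= total <= 9:
        return FiveTier.LPV
    if 0 <= total <= 5:
        return FiveTier.VUS
    if -5 <= total <= -1:
        return FiveTier.LBV
    return FiveTier.BV


def oracle_combine(evidence) -> FiveTier:
    """The combination rules applied literally, step by step."""
    if any(e.code is EvidenceCode.BA1 for e in evidence):
        return FiveTier.BV
    total = sum(e.points for e in evidence)
    pathogenic = [e for e in evidence if e.points > 0]
    if (
        len(pathogenic) == 1
        and pathogenic[0].code is EvidenceCode.PM2
        and categorize_literal(total - pathogenic[0].points)
        in (FiveTier.LBV, FiveTier.BV)
    ):
        total -= pathogenic[0].points
    category = categorize_literal(total)
    if category in (FiveTier.LBV, FiveTier.BV) and len(pathogenic) >= 2:
        return FiveTier.VUS
    return category


ORACLE_POOLS = [
    [E(EvidenceCode.PM2, Strength.SUPPORTING), E(EvidenceCode.PP3, Strength.SUPPORTING),
     E(EvidenceCode.PS3, Strength.STRONG), E(EvidenceCode.PM5, Strength.MODERATE),
     E(EvidenceCode.BP4, Strength.SUPPORTING), E(EvidenceCode.BS3, Strength.STRONG)],
    [E(EvidenceCode.BA1, Strength.STANDALONE), E(EvidenceCode.PP5, Strength.VERY_STRONG),
     E(EvidenceCode.PS4, Strength.STRONG), E(EvidenceCode.BP1, Strength.SUPPORTING),
     E(EvidenceCode.BP6, Strength.MODERATE), E(EvidenceCode.PM1, Strength.SUPPORTING)],
    [E(EvidenceCode.PM2, Strength.SUPPORTING), E(EvidenceCode.BP4, Strength.SUPPORTING),
     E(EvidenceCode.BP1, Strength.SUPPORTING), E(EvidenceCode.BS1, Strength.STRONG),
     E(EvidenceCode.PM1, Strength.MODERATE), E(EvidenceCode.PS1, Strength.STRONG)],
]


@pytest.mark.parametrize("pool", ORACLE_POOLS, ids=["mixed", "extreme", "benign-heavy"])
def test_combine_matches_subset_enumeration(pool):
    for r in range(len(pool) + 1):
        for subset in itertools.combinations(pool, r):
            result = combine_canvig(list(subset))
            assert result.category is oracle_combine(subset), subset
            if not any(e.code is EvidenceCode.BA1 for e in subset):
                expected_total = sum(e.points for e in subset)
                if Override.PM2_EXCLUDED in result.overrides_applied:
                    expected_total -= 1
                assert result.total_points == expected_total


# --- monotonicity & determinism ---------------------------------------------

_ORDER = [FiveTier.BV, FiveTier.LBV, FiveTier.VUS, FiveTier.LPV, FiveTier.PV]

PATHOGENIC_EXTRAS = [
    E(EvidenceCode.PP5, Strength.SUPPORTING), E(EvidenceCode.PS4, Strength.MODERATE),
    E(EvidenceCode.PS1, Strength.STRONG), E(EvidenceCode.PP5, Strength.VERY_STRONG),
]


@given(
    subset_index=st.integers(min_value=0, max_value=2**6 - 1),
    extra=st.sampled_from(PATHOGENIC_EXTRAS),
)
@settings(deadline=None, derandomize=True)
def test_adding_pathogenic_evidence_never_moves_toward_benign(subset_index, extra):
    pool = ORACLE_POOLS[0]
    subset = [e for i, e in enumerate(pool) if subset_index >> i & 1]
    if any(e.code is extra.code for e in subset):
        return
    before = combine_canvig(subset).category
    after = combine_canvig(subset + [extra]).category
    assert _ORDER.index(after) >= _ORDER.index(before)


def test_classification_is_deterministic(missense_variant):
    bundle = AnnotationBundle(
        revel=0.8, allele_count=0, allele_number=60_000, af=0.0,
        functional_result="abnormal", assay_strength=Strength.MODERATE,
    )
    first = classify_variant_canvig(missense_variant, bundle)
    second = classify_variant_canvig(missense_variant, bundle)
    assert first == second


# --- end to end -------------------------------------------------------------

def test_classify_absence_only_is_vus():
    result = classify_variant_canvig(
        variant_at(1200),
        AnnotationBundle(af=0.0, allele_count=0, allele_number=60_000, splice_score=0.5),
    )
    assert result.codes() == ("PM2",)
    assert result.total_points == 1 and result.category is FiveTier.VUS


def test_classify_empty_bundle_is_vus():
    # position outside domains with a splice signal blocking BP1: no evidence
    result = classify_variant_canvig(
        variant_at(1200), AnnotationBundle(splice_score=0.5)
    )
    assert result.evidence == () and result.total_points == 0
    assert result.category is FiveTier.VUS


def test_classify_common_variant_is_benign_by_standalone(missense_variant):
    result = classify_variant_canvig(
        missense_variant,
        AnnotationBundle(af=0.002, allele_count=200, allele_number=100_000),
    )
    assert result.category is FiveTier.BV
    assert Override.BA1_STANDALONE in result.overrides_applied


def test_non_missense_rejected():
    variant = VariantRecord(
        variant_id="splice1", gene="BRCA1", hgvs_c="c.1A>G", hgvs_p="p.?",
        protein_position=10, consequence=Consequence.OTHER,
    )
    with pytest.raises(ValueError, match="missense"):
        classify_variant_canvig(variant, AnnotationBundle())
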