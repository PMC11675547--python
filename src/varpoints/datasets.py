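"""Published summary counts for the 450 conflicting BRCA1 missense variants.

The underlying per-variant appendix of the published comparison is not
redistributable, but its printed summary tables are: the per-engine
three-tier classification counts, the cross-classification of the two
engines, the agreement strata by ClinVar submitter composition, and the
17 variants that later reached ClinVar consensus.  These count tables are
encoded here as package data so the analysis operations can be exercised
on the real cohort's summary structure without any download.

Expansion helpers rebuild aligned per-variant object lists that realize
the published counts exactly, for feeding through the analysis functions.
"""

from __future__ import annotations

from datetime import date

from .clinvar import (
    VariantSubmissionSet,
    normalize_consensus_label,
    normalize_label,
)
from .model import (
    Consequence,
    ConsolidatedTier,
    FiveTier,
    SubmissionRecord,
    VariantRecord,
)

N_COHORT = 450

#: Three-tier classification counts per engine (the published totals).
CLASSIFICATION_COUNTS: dict[str, dict[ConsolidatedTier, int]] = {
    "auto": {
        ConsolidatedTier.P_LP: 51,
        ConsolidatedTier.VUS: 111,
        ConsolidatedTier.B_LB: 288,
    },
    "canvig": {
        ConsolidatedTier.P_LP: 50,
        ConsolidatedTier.VUS: 232,
        ConsolidatedTier.B_LB: 168,
    },
}

#: Cross-classification cell counts (rows = automated engine, cols =
#: gene-specific engine).  The published figure's discordant cells are
#: inconsistent with its own marginals by one variant; this is the unique
#: completion consistent with both engines' marginal counts, the 265
#: concordant total, and the published 138-variant automated-benign /
#: gene-specific-VUS comparison.  Individual discordant cells are treated
#: as reconstruction, not as published fact.
CROSS_CLASSIFICATION: dict[tuple[ConsolidatedTier, ConsolidatedTier], int] = {
    (ConsolidatedTier.P_LP, ConsolidatedTier.P_LP): 36,
    (ConsolidatedTier.P_LP, ConsolidatedTier.VUS): 15,
    (ConsolidatedTier.P_LP, ConsolidatedTier.B_LB): 0,
    (ConsolidatedTier.VUS, ConsolidatedTier.P_LP): 14,
    (ConsolidatedTier.VUS, ConsolidatedTier.VUS): 79,
    (ConsolidatedTier.VUS, ConsolidatedTier.B_LB): 18,
    (ConsolidatedTier.B_LB, ConsolidatedTier.P_LP): 0,
    (ConsolidatedTier.B_LB, ConsolidatedTier.VUS): 138,
    (ConsolidatedTier.B_LB, ConsolidatedTier.B_LB): 150,
}

#: Agreement strata by ClinVar submitter composition: for each analysed
#: tier, (stratum label, stratum size, automated matches, gene-specific
#: matches).  The strata are a submitter majority, a non-majority
#: minority, and their union.
STRATIFIED_COUNTS: dict[ConsolidatedTier, list[tuple[str, int, int, int]]] = {
    ConsolidatedTier.P_LP: [
        (">50% of submitters", 21, 19, 20),
        ("<=50% of submitters", 34, 18, 30),
        ("at least 1 submitter", 55, 37, 50),
    ],
    ConsolidatedTier.B_LB: [
        (">50% of submitters", 66, 54, 48),
        ("<=50% of submitters", 329, 233, 120),
        ("at least 1 submitter", 395, 287, 168),
    ],
}

#: The 17 conflicting variants that reached ClinVar consensus by the later
#: snapshot: (hgvs_c, hgvs_p, total submissions, % PV/LPV, % VUS, % BV/LBV
#: at the first snapshot, automated-engine call, gene-specific call,
#: consensus label as printed).
CONSENSUS_UPDATE_ROWS: list[tuple[str, str, int, float, float, float, str, str, str]] = [
    ("c.811G>A", "p.Val271Met", 15, 0.0, 6.7, 93.3, "LBV", "LBV", "BV/LBV"),
    ("c.2207A>C", "p.Glu736Ala", 7, 0.0, 14.3, 85.7, "LBV", "LBV", "BV/LBV"),
    ("c.2735A>G", "p.Lys912Arg", 6, 0.0, 16.7, 83.3, "LBV", "LBV", "LBV"),
    ("c.4766G>A", "p.Arg1589His", 6, 0.0, 16.7, 83.3, "LBV", "LBV", "LBV"),
    ("c.3818A>G", "p.Gln1273Arg", 4, 0.0, 25.0, 75.0, "LBV", "LBV", "LBV"),
    ("c.5585A>T", "p.His1862Leu", 4, 0.0, 25.0, 75.0, "LBV", "VUS", "BV/LBV"),
    ("c.2155A>G", "p.Lys719Glu", 13, 0.0, 61.5, 38.5, "LBV", "LBV", "BV"),
    ("c.441G>C", "p.Leu147Phe", 7, 14.3, 85.7, 0.0, "VUS", "VUS", "VUS"),
    ("c.5521A>C", "p.Ser1841Arg", 5, 40.0, 60.0, 0.0, "LPV", "LPV", "LPV"),
    ("c.5165C>A", "p.Ser1722Tyr", 4, 50.0, 50.0, 0.0, "LPV", "LPV", "LPV"),
    ("c.5254G>C", "p.Ala1752Pro", 2, 50.0, 50.0, 0.0, "LPV", "LPV", "PV/LPV"),
    ("c.5362G>T", "p.Gly1788Cys", 2, 50.0, 50.0, 0.0, "PV", "LPV", "LPV"),
    ("c.5090G>A", "p.Cys1697Tyr", 3, 66.7, 33.3, 0.0, "PV", "LPV", "LPV"),
    ("c.5258G>C", "p.Arg1753Thr", 3, 66.7, 33.3, 0.0, "LP", "LPV", "PV/LPV"),
    ("c.5143A>T", "p.Ser1715Cys", 5, 80.0, 20.0, 0.0, "PV", "PV", "LPV"),
    ("c.5408G>C", "p.Gly1803Ala", 5, 80.0, 20.0, 0.0, "VUS", "LPV", "PV/LPV"),
    ("c.5332G>A", "p.Asp1778Asn", 6, 83.3, 16.7, 0.0, "PV", "LPV", "PV/LPV"),
]


def expand_cross_classification() -> tuple[list[ConsolidatedTier], list[ConsolidatedTier]]:
    """Aligned per-variant tier lists realizing the cross-classification counts."""
    auto: list[ConsolidatedTier] = []
    canvig: list[ConsolidatedTier] = []
    for (tier_a, tier_c), count in CROSS_CLASSIFICATION.items():
        auto.extend([tier_a] * count)
        canvig.extend([tier_c] * count)
    return auto, canvig


def consensus_update_table() -> tuple[
    list[str], list[FiveTier], list[FiveTier], list[ConsolidatedTier]
]:
    """Variant ids, both engines' five-tier calls and consolidated consensus tiers."""
    ids, auto, canvig, consensus = [], [], [], []
    for row in CONSENSUS_UPDATE_ROWS:
        hgvs_c, _, _, _, _, _, auto_label, canvig_label, consensus_label = row
        ids.append(hgvs_c)
        auto.append(normalize_label(auto_label))
        canvig.append(normalize_label(canvig_label))
        consensus.append(normalize_consensus_label(consensus_label))
    return ids, auto, canvig, consensus


def consensus_update_full_cohort() -> tuple[
    list[str], list[FiveTier], list[FiveTier], list[ConsolidatedTier | None]
]:
    """Consensus table padded to the full cohort size.

    The 433 variants that remained conflicting at the later snapshot carry
    a ``None`` consensus (their engine calls are irrelevant to the
    comparison and are filled with VUS placeholders), so the consensus
    fraction is computed over the whole 450-variant cohort.
    """
    ids, auto, canvig, consensus = consensus_update_table()
    n_pad = N_COHORT - len(ids)
    ids = ids + [f"unresolved_{i + 1}" for i in range(n_pad)]
    auto = auto + [FiveTier.VUS] * n_pad
    canvig = canvig + [FiveTier.VUS] * n_pad
    padded: list[ConsolidatedTier | None] = list(consensus) + [None] * n_pad
    return ids, auto, canvig, padded


def _make_variant(index: int, tier_hint: str) -> VariantRecord:
    return VariantRecord(
        variant_id=f"{tier_hint}_{index}",
        gene="BRCA1",
        hgvs_c=f"c.{index}A>G",
        hgvs_p=f"p.Xaa{index}Yaa",
        protein_position=index,
        consequence=Consequence.MISSENSE,
    )


def _submission(vid: str, k: int, tier: FiveTier) -> SubmissionRecord:
    return SubmissionRecord(
        variant_id=vid,
        submitter_id=f"sub{k}",
        classification=tier,
        assertion_criteria=True,
        snapshot_date=date(2022, 12, 20),
    )


def expand_stratified_cohort() -> tuple[
    list[VariantSubmissionSet], list[ConsolidatedTier], list[ConsolidatedTier]
]:
    """Per-variant submission sets and engine tiers realizing the strata counts.

    Variants with a pathogenic-voting submitter never overlap those with a
    benign-voting submitter in the published strata (21+34 = 55 and
    66+329 = 395 sum to the 450-variant cohort), so the cohort splits into
    two blocks.  Majority-stratum variants get a 2-of-3 submitter vote for
    the analysed tier, minority-stratum variants a 1-of-3 vote (both
    conflicting at the three-tier level); engine calls match the analysed
    tier for exactly the published number of variants, with non-matching
    calls placed in VUS except one automated-engine benign call among the
    pathogenic-voting block (as published).
    """
    sets: list[VariantSubmissionSet] = []
    auto: list[ConsolidatedTier] = []
    canvig: list[ConsolidatedTier] = []
    index = 0

    def add_block(
        tier: ConsolidatedTier,
        voted: FiveTier,
        filler: FiveTier,
        majority: bool,
        n: int,
        auto_match: int,
        canvig_match: int,
        auto_other: list[ConsolidatedTier] | None = None,
    ) -> None:
        nonlocal index
        votes = (
            [voted, voted, filler] if majority else [voted, filler, filler]
        )
        others = list(auto_other or [])
        for i in range(n):
            index += 1
            variant = _make_variant(index, tier.name.lower())
            subs = [
                _submission(variant.variant_id, k, v) for k, v in enumerate(votes)
            ]
            sets.append(VariantSubmissionSet(variant=variant, submissions=subs))
            auto.append(
                tier
                if i < auto_match
                else (others.pop() if others else ConsolidatedTier.VUS)
            )
            canvig.append(tier if i < canvig_match else ConsolidatedTier.VUS)

    for label, n, auto_match, canvig_match in STRATIFIED_COUNTS[ConsolidatedTier.P_LP]:
        if label.startswith("at least"):
            continue
        add_block(
            ConsolidatedTier.P_LP,
            FiveTier.PV,
            FiveTier.VUS,
            label.startswith(">"),
            n,
            auto_match,
            canvig_match,
            # one automated-engine benign call among the pathogenic-voting block
            auto_other=[ConsolidatedTier.B_LB] if label.startswith("<=") else None,
        )
    for label, n, auto_match, canvig_match in STRATIFIED_COUNTS[ConsolidatedTier.B_LB]:
        if label.startswith("at least"):
            continue
        add_block(
            ConsolidatedTier.B_LB,
            FiveTier.BV,
            FiveTier.VUS,
            label.startswith(">"),
            n,
            auto_match,
            canvig_match,
        )
    return sets, auto, canvig
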