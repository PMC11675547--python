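"""Cross-classifier agreement, stratified comparison and consensus follow-up.

Quantifies how two classification engines agree over a shared variant set:
a 3x3 confusion matrix on the consolidated tiers, the overall concordance
rate with an exact Clopper-Pearson binomial interval, per-tier
classification distributions, agreement stratified by how the ClinVar
submitter base voted, and comparison of engine calls against later
database consensus.

Printed percentages use one decimal with half-away-from-zero rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

from statsmodels.stats.proportion import proportion_confint

from .clinvar import VariantSubmissionSet, submitter_tier_fraction
from .model import (
    ClassificationResult,
    ConfusionMatrix,
    ConsolidatedTier,
    FiveTier,
    consolidate,
)

TIER_ORDER = ConfusionMatrix.TIER_ORDER


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of printed tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    sign = -1 if value < 0 else 1
    magnitude = Decimal(repr(abs(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(sign * magnitude)


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage to ``ndigits`` decimals, half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def _as_tier(item) -> ConsolidatedTier:
    if isinstance(item, ClassificationResult):
        return item.consolidated
    if isinstance(item, (FiveTier, ConsolidatedTier, str)):
        return consolidate(item)
    raise ValueError(f"cannot interpret {item!r} as a classification tier")


def build_confusion(
    a: Sequence, b: Sequence
) -> ConfusionMatrix:
    """Cross-tabulate two aligned tier sequences (rows = a, cols = b)."""
    if len(a) != len(b):
        raise ValueError(
            f"classification lists must align: {len(a)} vs {len(b)} entries"
        )
    matrix = ConfusionMatrix()
    for left, right in zip(a, b):
        i = TIER_ORDER.index(_as_tier(left))
        j = TIER_ORDER.index(_as_tier(right))
        matrix.counts[i][j] += 1
    return matrix


@dataclass(frozen=True)
class AgreementReport:
    """Overall agreement with an exact binomial confidence interval."""

    matrix: ConfusionMatrix
    concordance: float
    ci_low: float
    ci_high: float
    n: int
    confidence: float

    @property
    def concordance_percent(self) -> float:
        return percent(self.matrix.trace, self.n)


def concordance_rate(
    matrix: ConfusionMatrix, confidence: float = 0.95
) -> AgreementReport:
    """Trace over grand total with a Clopper-Pearson interval at ``confidence``."""
    n = matrix.grand_total
    if n < 1:
        raise ValueError("confusion matrix is empty")
    trace = matrix.trace
    low, high = proportion_confint(trace, n, alpha=1 - confidence, method="beta")
    return AgreementReport(
        matrix=matrix,
        concordance=trace / n,
        ci_low=float(low),
        ci_high=float(high),
        n=n,
        confidence=confidence,
    )


@dataclass(frozen=True)
class TierDistribution:
    """Per-tier counts and one-decimal percentages over the consolidated tiers."""

    counts: dict[ConsolidatedTier, int]
    percentages: dict[ConsolidatedTier, float]
    n: int


def classification_distribution(results: Iterable) -> TierDistribution:
    """Count consolidated tiers and report percentages to one decimal."""
    tiers = [_as_tier(r) for r in results]
    if not tiers:
        raise ValueError("no classification results given")
    counts = {tier: 0 for tier in TIER_ORDER}
    for tier in tiers:
        counts[tier] += 1
    n = len(tiers)
    return TierDistribution(
        counts=counts,
        percentages={tier: percent(counts[tier], n) for tier in TIER_ORDER},
        n=n,
    )


@dataclass(frozen=True)
class StratumRow:
    """One submitter-composition stratum with the engine's same-tier proportion."""

    label: str
    n: int
    matches: int
    match_percent: float | None  # None when the stratum is empty


def stratified_agreement(
    classifications: Sequence,
    sets: Sequence[VariantSubmissionSet],
    tier: ConsolidatedTier,
) -> list[StratumRow]:
    """Engine agreement with the submitter base, stratified by vote share.

    Three nested strata over variants with at least one assertion-criteria
    submission in ``tier``: a submitter majority (> 50%), a non-majority
    minority (<= 50% but at least one), and the union (at least one).
    For each, the proportion of stratum variants the engine itself places
    in ``tier``.
    """
    if len(classifications) != len(sets):
        raise ValueError(
            f"classifications and submission sets must align: "
            f"{len(classifications)} vs {len(sets)}"
        )
    half = Fraction(1, 2)
    strata: dict[str, list[bool]] = {
        ">50% of submitters": [],
        "<=50% of submitters": [],
        "at least 1 submitter": [],
    }
    for result, subset in zip(classifications, sets):
        fraction = submitter_tier_fraction(subset, tier)
        if fraction == 0:
            continue
        engine_match = _as_tier(result) is tier
        strata["at least 1 submitter"].append(engine_match)
        if fraction > half:
            strata[">50% of submitters"].append(engine_match)
        else:
            strata["<=50% of submitters"].append(engine_match)
    rows = []
    for label, hits in strata.items():
        n = len(hits)
        matches = sum(hits)
        rows.append(
            StratumRow(
                label=label,
                n=n,
                matches=matches,
                match_percent=percent(matches, n) if n else None,
            )
        )
    return rows


@dataclass(frozen=True)
class ConsensusMismatch:
    variant_id: str
    engine_tier: ConsolidatedTier
    consensus_tier: ConsolidatedTier


@dataclass(frozen=True)
class ConsensusReport:
    """Engine calls versus later database consensus, on consensus variants only."""

    tier_counts: dict[ConsolidatedTier, int]
    mismatches: list[ConsensusMismatch]
    n_consensus: int
    n_total: int

    @property
    def consensus_percent(self) -> float:
        return percent(self.n_consensus, self.n_total)


def consensus_comparison(
    engine_results: Sequence,
    consensus_tiers: Sequence[ConsolidatedTier | None],
    variant_ids: Sequence[str] | None = None,
) -> ConsensusReport:
    """Restrict to variants that reached consensus; count tiers and list disagreements."""
    if len(engine_results) != len(consensus_tiers):
        raise ValueError(
            f"engine results and consensus tiers must align: "
            f"{len(engine_results)} vs {len(consensus_tiers)}"
        )
    if variant_ids is None:
        variant_ids = [f"variant_{i + 1}" for i in range(len(engine_results))]
    tier_counts = {tier: 0 for tier in TIER_ORDER}
    mismatches: list[ConsensusMismatch] = []
    n_consensus = 0
    for vid, result, consensus in zip(variant_ids, engine_results, consensus_tiers):
        if consensus is None:
            continue
        n_consensus += 1
        tier_counts[consensus] += 1
        engine_tier = _as_tier(result)
        if engine_tier is not consensus:
            mismatches.append(
                ConsensusMismatch(
                    variant_id=vid,
                    engine_tier=engine_tier,
                    consensus_tier=consensus,
                )
            )
    return ConsensusReport(
        tier_counts=tier_counts,
        mismatches=mismatches,
        n_consensus=n_consensus,
        n_total=len(engine_results),
    )
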