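"""Core domain model for points-based germline variant classification.

The ACMG/AMP framework combines discrete evidence criteria — pathogenic
(PS/PM/PP) and benign (BA/BS/BP) — into a five-tier call: pathogenic (PV),
likely pathogenic (LPV), uncertain (VUS), likely benign (LBV), benign (BV).
In the points formulation each triggered criterion contributes a signed
integer (supporting 1, moderate 2, strong 4, very strong 8; benign
direction negative) and the total is mapped to a tier through a threshold
table.  Everything downstream — the gene-specific CanVIG-UK engine, the
automated generic engine, ClinVar submission bookkeeping and the
concordance analyses — shares the types defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date


class Consequence(enum.Enum):
    """Molecular consequence; the engines only classify missense changes."""

    MISSENSE = "missense"
    OTHER = "other"


class FiveTier(enum.Enum):
    """The five-tier pathogenicity call used by ClinVar submitters and both engines."""

    PV = "PV"
    LPV = "LPV"
    VUS = "VUS"
    LBV = "LBV"
    BV = "BV"


class ConsolidatedTier(enum.Enum):
    """Three broad categories used for cross-engine and consensus comparison."""

    P_LP = "PV/LPV"
    VUS = "VUS"
    B_LB = "BV/LBV"


_CONSOLIDATION = {
    FiveTier.PV: ConsolidatedTier.P_LP,
    FiveTier.LPV: ConsolidatedTier.P_LP,
    FiveTier.VUS: ConsolidatedTier.VUS,
    FiveTier.LBV: ConsolidatedTier.B_LB,
    FiveTier.BV: ConsolidatedTier.B_LB,
}


def consolidate(category: FiveTier | ConsolidatedTier | str) -> ConsolidatedTier:
    """Collapse a five-tier call into PV/LPV, VUS or BV/LBV.

    Accepts a :class:`FiveTier`, an already-consolidated tier (identity), or
    the string name of either.  Unknown labels are rejected with the
    offending label in the message.
    """
    if isinstance(category, ConsolidatedTier):
        return category
    if isinstance(category, str):
        try:
            category = FiveTier[category]
        except KeyError:
            try:
                return ConsolidatedTier[category]
            except KeyError:
                raise ValueError(f"unknown classification label: {category!r}") from None
    if not isinstance(category, FiveTier):
        raise ValueError(f"unknown classification label: {category!r}")
    return _CONSOLIDATION[category]


class EvidenceCode(enum.Enum):
    """ACMG/AMP evidence criteria handled by the engines (missense scope)."""

    PS1 = "PS1"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM5 = "PM5"
    PP3 = "PP3"
    PP5 = "PP5"
    BA1 = "BA1"
    BS1 = "BS1"
    BS3 = "BS3"
    BP1 = "BP1"
    BP3 = "BP3"
    BP4 = "BP4"
    BP6 = "BP6"

    @property
    def direction(self) -> "Direction":
        return Direction.PATHOGENIC if self.value.startswith("P") else Direction.BENIGN


class Direction(enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(enum.Enum):
    STANDALONE = "standalone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


#: Unsigned point value per graded strength; BA1's standalone strength is
#: carried at 8 points so totals stay well-defined even though its category
#: effect is an override, not arithmetic.
STRENGTH_POINTS: dict[Strength, int] = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
    Strength.STANDALONE: 8,
}

_POINTS_STRENGTH = {1: Strength.SUPPORTING, 2: Strength.MODERATE,
                    4: Strength.STRONG, 8: Strength.VERY_STRONG}


def points_to_strength(points: int) -> Strength:
    """Inverse of the graded strength→points map (sign ignored)."""
    try:
        return _POINTS_STRENGTH[abs(points)]
    except KeyError:
        raise ValueError(f"no graded strength carries {points} points") from None


class Override(enum.Enum):
    """Category overrides an engine may record on a classification."""

    PM2_EXCLUDED = "pm2_excluded"
    VUS_OVERRIDE = "vus_override"
    BA1_STANDALONE = "ba1_standalone"


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant in HGVS nomenclature with its protein position."""

    variant_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    protein_position: int
    consequence: Consequence = Consequence.MISSENSE

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise ValueError(
                f"{self.variant_id}: protein_position must be >= 1, "
                f"got {self.protein_position}"
            )


@dataclass(frozen=True)
class SameResidueRef:
    """A previously classified missense change at the same amino-acid residue."""

    hgvs_p: str
    classification: FiveTier
    revel: float | None = None
    limited_reports: bool = False

    def __post_init__(self) -> None:
        if self.classification not in (FiveTier.PV, FiveTier.LPV):
            raise ValueError(
                f"same-residue reference {self.hgvs_p} must be PV or LPV, "
                f"got {self.classification}"
            )
        _check_unit(self.revel, "revel")


def _check_unit(value: float | None, name: str) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class AnnotationBundle:
    """All per-variant evidence inputs consumed by the engines.

    Every field is optional; absence means the evidence source was not
    available for the variant, which is the norm in a conflicting-variant
    cohort (functional and multifactorial data are sparse).

    Parameters
    ----------
    af : gnomAD non-cancer female popmax allele frequency.
    allele_count, allele_number : observed allele count / total alleles
        behind ``af``; the frequency test operates on counts.
    revel, metarnn : ensemble in-silico missense deleteriousness scores in [0, 1].
    splice_score : predicted splice-impact score in [0, 1].
    functional_result : outcome of a well-established functional assay, with
        ``assay_strength`` giving the evidence grade the assay supports.
    multifactorial_lr : published multifactorial likelihood ratio toward
        pathogenicity (values > 1 favour pathogenic, < 1 benign).
    case_control_or : case-control odds ratio.
    same_residue_refs : previously classified missense changes at the residue.
    same_aa_change_pathogenic : an identical amino-acid change (different
        nucleotide) has an established pathogenic classification (PS1 input).
    repeat_region : variant falls in a repetitive region without known
        function (input trigger for the automated engine's BP3 behaviour).
    """

    af: float | None = None
    allele_count: int | None = None
    allele_number: int | None = None
    revel: float | None = None
    metarnn: float | None = None
    splice_score: float | None = None
    functional_result: str | None = None  # abnormal|normal|intermediate|splice_effect
    assay_strength: Strength | None = None
    multifactorial_lr: float | None = None
    case_control_or: float | None = None
    same_residue_refs: tuple[SameResidueRef, ...] = ()
    same_aa_change_pathogenic: bool = False
    repeat_region: bool = False

    _FUNCTIONAL_RESULTS = frozenset(
        {"abnormal", "normal", "intermediate", "splice_effect"}
    )

    def __post_init__(self) -> None:
        for name in ("af", "revel", "metarnn", "splice_score"):
            _check_unit(getattr(self, name), name)
        if self.allele_count is not None and self.allele_count < 0:
            raise ValueError(f"allele_count must be >= 0, got {self.allele_count}")
        if self.allele_number is not None and self.allele_number < 1:
            raise ValueError(f"allele_number must be >= 1, got {self.allele_number}")
        if (
            self.allele_count is not None
            and self.allele_number is not None
            and self.allele_count > self.allele_number
        ):
            raise ValueError(
                f"allele_count {self.allele_count} exceeds allele_number "
                f"{self.allele_number}"
            )
        if (
            self.functional_result is not None
            and self.functional_result not in self._FUNCTIONAL_RESULTS
        ):
            raise ValueError(
                f"unknown functional_result {self.functional_result!r}"
            )
        for name in ("multifactorial_lr", "case_control_or"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not isinstance(self.same_residue_refs, tuple):
            object.__setattr__(
                self, "same_residue_refs", tuple(self.same_residue_refs)
            )


@dataclass(frozen=True)
class EvidenceAssignment:
    """One triggered evidence criterion with its direction, strength and signed points."""

    code: EvidenceCode
    strength: Strength
    points: int
    note: str | None = None

    def __post_init__(self) -> None:
        expected = STRENGTH_POINTS[self.strength]
        if abs(self.points) != expected:
            raise ValueError(
                f"{self.code.value} at {self.strength.value} must carry "
                f"±{expected} points, got {self.points}"
            )
        sign_ok = (
            self.points > 0
            if self.direction is Direction.PATHOGENIC
            else self.points < 0
        )
        if not sign_ok:
            raise ValueError(
                f"{self.code.value} points must be "
                f"{'positive' if self.direction is Direction.PATHOGENIC else 'negative'},"
                f" got {self.points}"
            )
        if (self.strength is Strength.STANDALONE) != (self.code is EvidenceCode.BA1):
            raise ValueError("standalone strength is reserved for BA1")

    @property
    def direction(self) -> Direction:
        return self.code.direction

    @classmethod
    def make(
        cls, code: EvidenceCode, strength: Strength, note: str | None = None
    ) -> "EvidenceAssignment":
        """Build an assignment with the sign implied by the code's direction."""
        magnitude = STRENGTH_POINTS[strength]
        sign = 1 if code.direction is Direction.PATHOGENIC else -1
        return cls(code=code, strength=strength, points=sign * magnitude, note=note)


@dataclass(frozen=True)
class ClassificationResult:
    """Five-tier call with its point total, applied evidence and any overrides."""

    category: FiveTier
    total_points: int
    evidence: tuple[EvidenceAssignment, ...]
    overrides_applied: tuple[Override, ...] = ()

    @property
    def consolidated(self) -> ConsolidatedTier:
        return consolidate(self.category)

    def codes(self) -> tuple[str, ...]:
        return tuple(e.code.value for e in self.evidence)


@dataclass(frozen=True)
class SubmissionRecord:
    """One ClinVar submitter assertion for one variant at one snapshot date."""

    variant_id: str
    submitter_id: str
    classification: FiveTier
    assertion_criteria: bool
    snapshot_date: date


@dataclass
class ConfusionMatrix:
    """3x3 agreement grid between two classifiers over the consolidated tiers.

    Rows are classifier A, columns classifier B, both in the fixed order
    (PV/LPV, VUS, BV/LBV).
    """

    counts: list[list[int]] = field(
        default_factory=lambda: [[0] * 3 for _ in range(3)]
    )

    TIER_ORDER = (ConsolidatedTier.P_LP, ConsolidatedTier.VUS, ConsolidatedTier.B_LB)

    def __post_init__(self) -> None:
        if len(self.counts) != 3 or any(len(row) != 3 for row in self.counts):
            raise ValueError("counts must be a 3x3 grid")
        for row in self.counts:
            for cell in row:
                if cell < 0 or cell != int(cell):
                    raise ValueError(f"cell counts must be non-negative integers, got {cell}")

    @property
    def row_totals(self) -> list[int]:
        return [sum(row) for row in self.counts]

    @property
    def col_totals(self) -> list[int]:
        return [sum(row[j] for row in self.counts) for j in range(3)]

    @property
    def grand_total(self) -> int:
        return sum(self.row_totals)

    @property
    def trace(self) -> int:
        return sum(self.counts[i][i] for i in range(3))

    def cell(self, a: ConsolidatedTier, b: ConsolidatedTier) -> int:
        return self.counts[self.TIER_ORDER.index(a)][self.TIER_ORDER.index(b)]
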