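"""Ingest and analysis of ClinVar-style per-submission tables.

Reads a simplified, tab-delimited submission dialect (one row per
submitter assertion), normalizes free-text five-tier labels, groups rows
into per-variant submission sets, selects conflicting missense variants,
and detects later consensus.  "Conflicting" means at least two
assertion-criteria submissions disagreeing at the consolidated three-tier
level (so PV vs LPV is not a conflict); submissions without assertion
criteria are never counted, for conflicts, fractions, or consensus alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from fractions import Fraction

import pandas as pd

from .model import (
    Consequence,
    ConsolidatedTier,
    FiveTier,
    SubmissionRecord,
    VariantRecord,
    consolidate,
)

REQUIRED_COLUMNS = (
    "variant_id",
    "gene",
    "hgvs_c",
    "hgvs_p",
    "protein_position",
    "consequence",
    "submitter_id",
    "classification",
    "assertion_criteria",
    "snapshot_date",
)

#: Free-text label → five-tier enum (case-insensitive; covers ClinVar
#: spellings and the short forms seen in published tables, e.g. "LP").
_LABEL_MAP = {
    "pathogenic": FiveTier.PV,
    "pv": FiveTier.PV,
    "p": FiveTier.PV,
    "likely pathogenic": FiveTier.LPV,
    "likely-pathogenic": FiveTier.LPV,
    "lpv": FiveTier.LPV,
    "lp": FiveTier.LPV,
    "uncertain significance": FiveTier.VUS,
    "variant of uncertain significance": FiveTier.VUS,
    "vus": FiveTier.VUS,
    "likely benign": FiveTier.LBV,
    "likely-benign": FiveTier.LBV,
    "lbv": FiveTier.LBV,
    "lb": FiveTier.LBV,
    "benign": FiveTier.BV,
    "bv": FiveTier.BV,
    "b": FiveTier.BV,
}

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def normalize_label(label: str) -> FiveTier:
    """Map a free-text classification label to the five-tier enum."""
    try:
        return _LABEL_MAP[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown classification label: {label!r}") from None


def normalize_consensus_label(label: str) -> ConsolidatedTier:
    """Map a consensus-column label (five-tier or slashed pair) to a tier."""
    text = str(label).strip().lower()
    slashed = {
        "pv/lpv": ConsolidatedTier.P_LP,
        "lpv/pv": ConsolidatedTier.P_LP,
        "bv/lbv": ConsolidatedTier.B_LB,
        "lbv/bv": ConsolidatedTier.B_LB,
    }
    if text in slashed:
        return slashed[text]
    return consolidate(normalize_label(text))


@dataclass
class RowError:
    """A malformed input row, addressed by its 1-based line number."""

    line: int
    message: str


@dataclass
class VariantSubmissionSet:
    """All submissions for one variant at one snapshot date."""

    variant: VariantRecord
    submissions: list[SubmissionRecord]

    def __post_init__(self) -> None:
        if not self.submissions:
            raise ValueError(f"{self.variant.variant_id}: needs >= 1 submission")
        ids = {s.variant_id for s in self.submissions}
        if ids != {self.variant.variant_id}:
            raise ValueError(
                f"submission set mixes variant ids: {sorted(ids)}"
            )

    @property
    def countable(self) -> list[SubmissionRecord]:
        """Submissions with assertion criteria specified — the only ones counted."""
        return [s for s in self.submissions if s.assertion_criteria]


@dataclass
class ParseResult:
    sets: list[VariantSubmissionSet]
    errors: list[RowError] = field(default_factory=list)


def _parse_bool(raw: object) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _parse_date(raw: object) -> date:
    return date.fromisoformat(str(raw).strip())


def parse_submission_table(path) -> ParseResult:
    """Read a tab-delimited submission table into grouped, validated sets.

    Lines beginning with ``#`` are comments.  Rows that fail validation
    are collected as :class:`RowError` with their line number and do not
    abort the parse; a missing required column does.
    """
    frame = pd.read_csv(
        path, sep="\t", dtype=str, comment="#", keep_default_na=False
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if frame.empty:
        return ParseResult(sets=[])

    errors: list[RowError] = []
    grouped: dict[str, list[SubmissionRecord]] = {}
    variants: dict[str, VariantRecord] = {}
    order: list[str] = []
    # 1-based line numbers counting the header as line 1 (comment lines
    # before the header shift numbering; the common case has none).
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        try:
            vid = row["variant_id"].strip()
            if not vid:
                raise ValueError("empty variant_id")
            classification = normalize_label(row["classification"])
            record = SubmissionRecord(
                variant_id=vid,
                submitter_id=row["submitter_id"].strip(),
                classification=classification,
                assertion_criteria=_parse_bool(row["assertion_criteria"]),
                snapshot_date=_parse_date(row["snapshot_date"]),
            )
            if vid not in variants:
                consequence = (
                    Consequence.MISSENSE
                    if row["consequence"].strip().lower() == "missense"
                    else Consequence.OTHER
                )
                variants[vid] = VariantRecord(
                    variant_id=vid,
                    gene=row["gene"].strip(),
                    hgvs_c=row["hgvs_c"].strip(),
                    hgvs_p=row["hgvs_p"].strip(),
                    protein_position=int(row["protein_position"]),
                    consequence=consequence,
                )
                order.append(vid)
        except (ValueError, KeyError) as exc:
            errors.append(RowError(line=line, message=str(exc)))
            continue
        grouped.setdefault(vid, []).append(record)

    sets = [
        VariantSubmissionSet(variant=variants[vid], submissions=grouped[vid])
        for vid in order
        if vid in grouped
    ]
    return ParseResult(sets=sets, errors=errors)


def read_vcf_identities(path) -> list[dict]:
    """Extract variant identity fields from a VCF (id, chrom, pos, ref, alt).

    Convenience ingest only: protein-level annotation still has to come
    from an annotation table, so the result is not a :class:`VariantRecord`.
    """
    from cyvcf2 import VCF

    out = []
    for record in VCF(str(path)):
        for alt in record.ALT:
            out.append(
                {
                    "variant_id": record.ID or f"{record.CHROM}:{record.POS}:{record.REF}:{alt}",
                    "chrom": record.CHROM,
                    "pos": record.POS,
                    "ref": record.REF,
                    "alt": alt,
                }
            )
    return out


def is_conflicting(subset: VariantSubmissionSet) -> bool:
    """True iff >= 2 assertion-criteria submissions span >= 2 consolidated tiers."""
    countable = subset.countable
    if len(countable) < 2:
        return False
    tiers = {consolidate(s.classification) for s in countable}
    return len(tiers) >= 2


def select_conflicting_missense(
    sets: list[VariantSubmissionSet],
) -> list[VariantSubmissionSet]:
    """Missense variants with conflicting interpretations, order preserved."""
    return [
        s
        for s in sets
        if s.variant.consequence is Consequence.MISSENSE and is_conflicting(s)
    ]


def submitter_tier_fraction(
    subset: VariantSubmissionSet, tier: ConsolidatedTier
) -> Fraction:
    """Exact fraction of assertion-criteria submissions consolidating to ``tier``."""
    countable = subset.countable
    if not countable:
        raise ValueError(
            f"{subset.variant.variant_id}: no assertion-criteria submissions to count"
        )
    hits = sum(1 for s in countable if consolidate(s.classification) is tier)
    return Fraction(hits, len(countable))


def detect_consensus(subset: VariantSubmissionSet) -> ConsolidatedTier | None:
    """The single consolidated tier all countable submissions agree on, else None."""
    countable = subset.countable
    if not countable:
        raise ValueError(
            f"{subset.variant.variant_id}: no assertion-criteria submissions to count"
        )
    tiers = {consolidate(s.classification) for s in countable}
    if len(tiers) == 1:
        return next(iter(tiers))
    return None
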