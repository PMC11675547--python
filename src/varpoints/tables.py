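"""Tab-delimited table IO for cohorts, annotations and classification results.

All tables are UTF-8 TSV with a header row; lines starting with ``#`` are
comments (the writers record the generating seed there).  Same-residue
references are packed into one column as ``hgvs_p:classification:revel:limited``
entries joined by ``|``.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .clinvar import VariantSubmissionSet, normalize_label
from .model import (
    AnnotationBundle,
    Consequence,
    FiveTier,
    SameResidueRef,
    Strength,
    VariantRecord,
)

ANNOTATION_COLUMNS = (
    "variant_id", "gene", "hgvs_c", "hgvs_p", "protein_position", "consequence",
    "af", "allele_count", "allele_number", "revel", "metarnn", "splice_score",
    "functional_result", "assay_strength", "multifactorial_lr",
    "case_control_or", "repeat_region", "same_aa_change_pathogenic",
    "same_residue_refs",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (Strength, FiveTier, Consequence)):
        return value.value if not isinstance(value, (FiveTier,)) else value.name
    return str(value)


def _pack_refs(refs: tuple[SameResidueRef, ...]) -> str:
    return "|".join(
        f"{r.hgvs_p}:{r.classification.name}:"
        f"{'' if r.revel is None else repr(r.revel)}:"
        f"{'1' if r.limited_reports else '0'}"
        for r in refs
    )


def _unpack_refs(text: str) -> tuple[SameResidueRef, ...]:
    if not text:
        return ()
    refs = []
    for chunk in text.split("|"):
        hgvs_p, cls, revel, limited = chunk.split(":")
        refs.append(
            SameResidueRef(
                hgvs_p=hgvs_p,
                classification=normalize_label(cls),
                revel=float(revel) if revel else None,
                limited_reports=limited == "1",
            )
        )
    return tuple(refs)


def write_annotation_table(
    path: str | Path,
    variants: list[VariantRecord],
    bundles: list[AnnotationBundle],
    seed: int | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        handle.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for variant, bundle in zip(variants, bundles):
            row = [
                variant.variant_id, variant.gene, variant.hgvs_c, variant.hgvs_p,
                str(variant.protein_position), variant.consequence.value,
                _fmt(bundle.af), _fmt(bundle.allele_count), _fmt(bundle.allele_number),
                _fmt(bundle.revel), _fmt(bundle.metarnn), _fmt(bundle.splice_score),
                _fmt(bundle.functional_result),
                bundle.assay_strength.value if bundle.assay_strength else "",
                _fmt(bundle.multifactorial_lr), _fmt(bundle.case_control_or),
                _fmt(bundle.repeat_region), _fmt(bundle.same_aa_change_pathogenic),
                _pack_refs(bundle.same_residue_refs),
            ]
            handle.write("\t".join(row) + "\n")


def _opt_float(raw: str) -> float | None:
    raw = raw.strip()
    if not raw:
        return None
    value = float(raw)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value: {raw!r}")
    return value


def _opt_int(raw: str) -> int | None:
    raw = raw.strip()
    return int(raw) if raw else None


def read_annotation_table(
    path: str | Path,
) -> tuple[list[VariantRecord], list[AnnotationBundle]]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    variants, bundles = [], []
    for _, row in frame.iterrows():
        variants.append(
            VariantRecord(
                variant_id=row["variant_id"],
                gene=row["gene"],
                hgvs_c=row["hgvs_c"],
                hgvs_p=row["hgvs_p"],
                protein_position=int(row["protein_position"]),
                consequence=(
                    Consequence.MISSENSE
                    if row["consequence"].strip().lower() == "missense"
                    else Consequence.OTHER
                ),
            )
        )
        strength_raw = row["assay_strength"].strip()
        bundles.append(
            AnnotationBundle(
                af=_opt_float(row["af"]),
                allele_count=_opt_int(row["allele_count"]),
                allele_number=_opt_int(row["allele_number"]),
                revel=_opt_float(row["revel"]),
                metarnn=_opt_float(row["metarnn"]),
                splice_score=_opt_float(row["splice_score"]),
                functional_result=row["functional_result"].strip() or None,
                assay_strength=Strength(strength_raw) if strength_raw else None,
                multifactorial_lr=_opt_float(row["multifactorial_lr"]),
                case_control_or=_opt_float(row["case_control_or"]),
                repeat_region=row["repeat_region"].strip().lower() == "true",
                same_aa_change_pathogenic=(
                    row["same_aa_change_pathogenic"].strip().lower() == "true"
                ),
                same_residue_refs=_unpack_refs(row["same_residue_refs"].strip()),
            )
        )
    return variants, bundles


def write_submission_table(
    path: str | Path, sets: list[VariantSubmissionSet], seed: int | None = None
) -> None:
    """Write submission sets in the dialect :func:`varpoints.clinvar.parse_submission_table` reads."""
    with open(path, "w", encoding="utf-8") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        handle.write(
            "variant_id\tgene\thgvs_c\thgvs_p\tprotein_position\tconsequence\t"
            "submitter_id\tclassification\tassertion_criteria\tsnapshot_date\n"
        )
        for subset in sets:
            v = subset.variant
            for sub in subset.submissions:
                handle.write(
                    "\t".join(
                        [
                            v.variant_id, v.gene, v.hgvs_c, v.hgvs_p,
                            str(v.protein_position), v.consequence.value,
                            sub.submitter_id, sub.classification.name,
                            "true" if sub.assertion_criteria else "false",
                            sub.snapshot_date.isoformat(),
                        ]
                    )
                    + "\n"
                )


def write_classification_table(path: str | Path, variants, results) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(
            "variant_id\tcategory\tconsolidated\ttotal_points\tevidence\toverrides\n"
        )
        for variant, result in zip(variants, results):
            evidence = ",".join(
                f"{e.code.value}({e.strength.value}{'' if e.note is None else ':' + e.note})"
                for e in result.evidence
            )
            overrides = ",".join(o.value for o in result.overrides_applied)
            handle.write(
                f"{variant.variant_id}\t{result.category.name}\t"
                f"{result.consolidated.name}\t{result.total_points}\t"
                f"{evidence}\t{overrides}\n"
            )


def read_classification_table(path: str | Path) -> tuple[list[str], list[FiveTier]]:
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for column in ("variant_id", "category"):
        if column not in frame.columns:
            raise ValueError(f"missing required column(s): {column}")
    ids = list(frame["variant_id"])
    tiers = [normalize_label(c) for c in frame["category"]]
    return ids, tiers
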