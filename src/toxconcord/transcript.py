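"""Transcript-level evidence from pathway-analysis annotation exports.

The pipeline does not re-derive a commercial knowledge base; it ingests the
spreadsheet exports such tools produce — one record per disease-or-function
annotation with its category and overlap p-value — or synthetic equivalents
built from the hypergeometric overlap statistic.  Records are filtered to
liver/kidney relevance, collapsed to one row per category (carrying the most
significant annotation p-value by default) and graded with the p-value
matrix: very strong <= 0.0005, strong <= 0.005, medium <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import AbstractSet, Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .grades import EvidenceGrade
from .pathways import fisher_overlap

logger = logging.getLogger(__name__)

INPUT_SCOPES = ("liver_panel", "kidney_panel", "combined")


@dataclass(frozen=True)
class AnnotationRecord:
    substance: str
    input_scope: str  # liver_panel | kidney_panel | combined
    category: str
    annotation: str
    p_overlap: float
    n_deg: int = 0
    deg_names: Tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.0 < self.p_overlap <= 1.0):
            raise ValueError(f"p_overlap must be in (0, 1], got {self.p_overlap}")
        if not self.category:
            raise ValueError("category must be non-empty")


@dataclass(frozen=True)
class CategoryEvidence:
    substance: str
    input_scope: str
    category: str
    best_p: float
    grade: EvidenceGrade


def filter_ipa_input(
    expr: pd.DataFrame, fr_cutoff: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Rows strong enough to enter pathway analysis:
    |fold regulation| >= fr_cutoff and p <= alpha."""
    if expr.empty:
        return expr
    mask = (
        (expr["fold_regulation"].abs() >= fr_cutoff)
        & (expr["p_value"] <= alpha)
        & expr["p_value"].notna()
    )
    dropped = int((~mask).sum())
    if dropped:
        logger.info(
            "filter_ipa_input: %d rows removed (reason=below_fr_or_p_cutoff, fr>=%s, p<=%s)",
            dropped, fr_cutoff, alpha,
        )
    return expr.loc[mask].reset_index(drop=True)


def filter_organ_categories(
    records: Iterable[AnnotationRecord], whitelist: AbstractSet[str]
) -> List[AnnotationRecord]:
    """Keep only liver/kidney-relevant categories; predictions for other
    organs (heart, lung, ...) are discarded."""
    kept, dropped = [], 0
    for rec in records:
        if rec.category in whitelist:
            kept.append(rec)
        else:
            dropped += 1
    if dropped:
        logger.info(
            "filter_organ_categories: %d records discarded (reason=non_hepatic_non_renal)",
            dropped,
        )
    return kept


def collapse_to_category(
    records: Iterable[AnnotationRecord], rule: str = "min_p"
) -> List[Tuple[str, str, str, float]]:
    """One (substance, input_scope, category, best_p) row per category.

    ``min_p`` keeps the most significant annotation within the category;
    ``max_p`` keeps the literal numerically largest p-value (available for
    sensitivity analysis).
    """
    if rule not in ("min_p", "max_p"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    best: Dict[Tuple[str, str, str], float] = {}
    pick = min if rule == "min_p" else max
    for rec in records:
        key = (rec.substance, rec.input_scope, rec.category)
        best[key] = pick(best[key], rec.p_overlap) if key in best else rec.p_overlap
    return [(s, sc, c, p) for (s, sc, c), p in sorted(best.items())]


def grade_category(
    best_p: float, thresholds: Tuple[float, float, float] = (0.0005, 0.005, 0.05)
) -> EvidenceGrade:
    """p-value matrix: the smaller the overlap p, the stronger the call."""
    very, strong, medium = thresholds
    if best_p <= very:
        return EvidenceGrade.VERY_STRONG
    if best_p <= strong:
        return EvidenceGrade.STRONG
    if best_p <= medium:
        return EvidenceGrade.MEDIUM
    return EvidenceGrade.NONE


def evaluate_annotations(
    records: Iterable[AnnotationRecord],
    whitelist: AbstractSet[str],
    thresholds: Tuple[float, float, float] = (0.0005, 0.005, 0.05),
    rule: str = "min_p",
) -> List[CategoryEvidence]:
    """Filter -> collapse -> grade."""
    kept = filter_organ_categories(records, whitelist)
    out = []
    for substance, scope, category, best_p in collapse_to_category(kept, rule):
        out.append(
            CategoryEvidence(
                substance=substance,
                input_scope=scope,
                category=category,
                best_p=best_p,
                grade=grade_category(best_p, thresholds),
            )
        )
    return out


def build_annotation_records(
    deg: AbstractSet[str],
    category_sets: Mapping[str, AbstractSet[str]],
    background: AbstractSet[str],
    substance: str,
    input_scope: str,
) -> List[AnnotationRecord]:
    """Synthetic annotation export from a DEG list and category gene sets.

    A transparent stand-in for a commercial knowledge-base export: each
    category contributes one annotation whose p-value of overlap is the
    right-tail hypergeometric probability of its gene-set overlap with the
    DEG list.
    """
    records = []
    for category in sorted(category_sets):
        genes = set(category_sets[category]) & set(background)
        if not genes:
            continue
        overlap = sorted(set(deg) & genes)
        p = fisher_overlap(set(deg) & set(background), genes, background)
        records.append(
            AnnotationRecord(
                substance=substance,
                input_scope=input_scope,
                category=category,
                annotation=category,
                p_overlap=p,
                n_deg=len(overlap),
                deg_names=tuple(overlap),
            )
        )
    return records


def category_evidence_to_frame(evidence: Sequence[CategoryEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "substance": e.substance,
                "input_scope": e.input_scope,
                "category": e.category,
                "best_p": e.best_p,
                "grade": e.grade.name,
            }
            for e in evidence
        ],
        columns=["substance", "input_scope", "category", "best_p", "grade"],
    )
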