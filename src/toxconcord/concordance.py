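"""Mapping graded in vitro evidence onto in vivo effect categories and
scoring indicative concordance.

The engine evaluates (substance, organ, effect-category) triples.  An in
vitro endpoint — a protein-marker cellular function, or a pathway-analysis
disease/function category — contributes a prediction for every effect
category it maps to, provided its evidence grade reaches the active
threshold.  Mapping rows whose key is a combination of several categories
fire only when every member passes the threshold, and contribute at the
weakest member's grade.

Indicative concordance is the percentage of in vivo-positive triples with a
positive in vitro prediction; negative agreement is the percentage of in
vivo-negative triples without one.  By default the evaluation universe is
restricted to effect categories reachable by at least one mapping row of the
active scope — the test system is not scored on endpoints it cannot express.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .grades import SWEEP_THRESHOLDS, EvidenceGrade

logger = logging.getLogger(__name__)

ORGANS = ("liver", "kidney")

#: report scopes: data type x cell-line combination
SCOPES = (
    "protein:HepaRG",
    "protein:RPTEC",
    "protein:combined",
    "mRNA:HepaRG",
    "mRNA:RPTEC",
    "mRNA:combined",
    "combined:combined",
)

#: organ(s) each cell line stands for in organ-matched scopes
CELL_LINE_ORGAN = {"HepaRG": "liver", "RPTEC": "kidney"}
INPUT_SCOPE_ORGAN = {"liver_panel": "liver", "kidney_panel": "kidney"}


@dataclass(frozen=True)
class MappingRule:
    """One row of an endpoint-to-effect ontology.

    ``members`` lists the endpoint keys that must all pass the grade
    threshold for the row to fire (a single key for ordinary rows).
    ``targets`` may be empty: some endpoints have no accepted in vivo
    counterpart and can never contribute a prediction.
    """

    members: Tuple[str, ...]
    organ: str
    targets: FrozenSet[str]

    def __post_init__(self):
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")


@dataclass
class EffectMapping:
    """A set of mapping rules of one kind ('protein' or 'category')."""

    kind: str
    rules: List[MappingRule]

    def endpoints(self) -> FrozenSet[str]:
        out = set()
        for r in self.rules:
            out.update(r.members)
        return frozenset(out)

    def reachable_effects(self, organ: str) -> FrozenSet[str]:
        """Effect categories that at least one rule can predict for *organ*."""
        out = set()
        for r in self.rules:
            if r.organ == organ:
                out.update(r.targets)
        return frozenset(out)

    def targets_for(self, endpoint: str, organ: str) -> FrozenSet[str]:
        out = set()
        for r in self.rules:
            if r.organ == organ and r.members == (endpoint,):
                out.update(r.targets)
        return frozenset(out)


@dataclass
class InVivoProfile:
    """Observed in vivo effect categories per substance and organ.

    Absence of a category from a substance's row is treated as an observed
    negative.  Categories listed under ``unknown`` are excluded from scoring
    entirely (unused by the packaged registry).
    """

    effects: Dict[str, Dict[str, FrozenSet[str]]]
    unknown: Dict[str, Dict[str, FrozenSet[str]]] = field(default_factory=dict)

    @property
    def substances(self) -> List[str]:
        return sorted(self.effects)

    def observed(self, substance: str, organ: str) -> FrozenSet[str]:
        return self.effects.get(substance, {}).get(organ, frozenset())

    def is_unknown(self, substance: str, organ: str, effect: str) -> bool:
        return effect in self.unknown.get(substance, {}).get(organ, frozenset())


# ---------------------------------------------------------------------------
# prediction sets

#: (substance, organ) -> effect -> (best grade, contributing endpoint keys)
PredictionSet = Dict[Tuple[str, str], Dict[str, Tuple[EvidenceGrade, Tuple[str, ...]]]]


def _endpoint_grades(evidence: Iterable, key_attr: str) -> Dict[str, Dict[str, EvidenceGrade]]:
    """substance -> endpoint -> best grade over the supplied evidence."""
    out: Dict[str, Dict[str, EvidenceGrade]] = {}
    for ev in evidence:
        sub = ev.substance
        key = getattr(ev, key_attr)
        grades = out.setdefault(sub, {})
        g = EvidenceGrade(ev.grade)
        if g > grades.get(key, EvidenceGrade.NONE):
            grades[key] = g
    return out


def map_predictions(
    evidence: Iterable,
    mapping: EffectMapping,
    threshold: EvidenceGrade,
    organs: Sequence[str] = ORGANS,
) -> PredictionSet:
    """Project graded evidence through *mapping* at a grade threshold.

    ``evidence`` items need ``substance``, ``grade`` and an endpoint key
    attribute (``cellular_function`` for protein evidence, ``category`` for
    transcript evidence).  A combination rule fires when all members reach
    the threshold, at the weakest member's grade.
    """
    key_attr = "cellular_function" if mapping.kind == "protein" else "category"
    grades = _endpoint_grades(evidence, key_attr)
    threshold = EvidenceGrade(threshold)

    preds: PredictionSet = {}
    for substance, endpoint_grades in grades.items():
        for rule in mapping.rules:
            if rule.organ not in organs or not rule.targets:
                continue
            member_grades = [endpoint_grades.get(m, EvidenceGrade.NONE) for m in rule.members]
            fired = min(member_grades)
            if fired < threshold:
                continue
            slot = preds.setdefault((substance, rule.organ), {})
            for effect in rule.targets:
                prev_grade, prev_src = slot.get(effect, (EvidenceGrade.NONE, ()))
                src = tuple(sorted(set(prev_src) | set(rule.members)))
                slot[effect] = (max(prev_grade, fired), src)
    return preds


def combine_scopes(prediction_sets: Sequence[PredictionSet]) -> PredictionSet:
    """OR-combination: union of predictions, best grade per effect."""
    out: PredictionSet = {}
    for pset in prediction_sets:
        for key, effects in pset.items():
            slot = out.setdefault(key, {})
            for effect, (grade, src) in effects.items():
                prev_grade, prev_src = slot.get(effect, (EvidenceGrade.NONE, ()))
                slot[effect] = (max(prev_grade, grade), tuple(sorted(set(prev_src) | set(src))))
    return out


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ConcordanceReport:
    """Counts and percentages for one scope x threshold cell."""

    scope: str
    threshold: EvidenceGrade
    n_pos: int
    n_hit: int
    n_neg: int
    n_correct_neg: int

    @property
    def indicative_concordance(self) -> Optional[float]:
        if self.n_pos == 0:
            return None
        return 100.0 * self.n_hit / self.n_pos

    @property
    def negative_agreement(self) -> Optional[float]:
        if self.n_neg == 0:
            return None
        return 100.0 * self.n_correct_neg / self.n_neg

    def rounded(self) -> Dict[str, Optional[int]]:
        """Integer display percentages, as printed in summary tables."""
        ic, na = self.indicative_concordance, self.negative_agreement
        return {
            "indicative_concordance": None if ic is None else round(ic),
            "negative_agreement": None if na is None else round(na),
        }

    def to_dict(self) -> Dict:
        return {
            "scope": self.scope,
            "threshold": self.threshold.name,
            "n_pos": self.n_pos,
            "n_hit": self.n_hit,
            "n_neg": self.n_neg,
            "n_correct_neg": self.n_correct_neg,
            "indicative_concordance": self.indicative_concordance,
            "negative_agreement": self.negative_agreement,
        }


def compute_concordance(
    predicted: PredictionSet,
    observed: InVivoProfile,
    mapping: EffectMapping | Sequence[EffectMapping],
    scope: str = "custom",
    threshold: EvidenceGrade = EvidenceGrade.MEDIUM,
    organs: Sequence[str] = ORGANS,
    substances: Optional[Sequence[str]] = None,
    include_unmapped: bool = False,
) -> Tuple[ConcordanceReport, pd.DataFrame]:
    """Score predictions against the in vivo registry.

    Returns the report and a per-triple audit table (substance, organ,
    effect, observed, predicted, grade, contributing endpoints).
    """
    mappings = [mapping] if isinstance(mapping, EffectMapping) else list(mapping)
    if substances is None:
        substances = observed.substances

    rows = []
    n_pos = n_hit = n_neg = n_correct_neg = 0
    for substance in substances:
        for organ in organs:
            reachable = set()
            for m in mappings:
                reachable |= m.reachable_effects(organ)
            universe = set(reachable)
            if include_unmapped:
                universe |= set(observed.observed(substance, organ))
            slot = predicted.get((substance, organ), {})
            for effect in sorted(universe):
                if observed.is_unknown(substance, organ, effect):
                    continue
                is_obs = effect in observed.observed(substance, organ)
                grade, src = slot.get(effect, (EvidenceGrade.NONE, ()))
                is_pred = effect in slot
                if is_obs:
                    n_pos += 1
                    n_hit += int(is_pred)
                else:
                    n_neg += 1
                    n_correct_neg += int(not is_pred)
                rows.append(
                    {
                        "scope": scope,
                        "threshold": EvidenceGrade(threshold).name,
                        "substance": substance,
                        "organ": organ,
                        "effect": effect,
                        "observed": is_obs,
                        "predicted": is_pred,
                        "grade": grade.name,
                        "contributors": ";".join(src),
                    }
                )

    report = ConcordanceReport(
        scope=scope,
        threshold=EvidenceGrade(threshold),
        n_pos=n_pos,
        n_hit=n_hit,
        n_neg=n_neg,
        n_correct_neg=n_correct_neg,
    )
    if n_pos + n_neg == 0:
        logger.warning("empty evaluation universe for scope %s", scope)
    audit = pd.DataFrame(
        rows,
        columns=[
            "scope", "threshold", "substance", "organ", "effect",
            "observed", "predicted", "grade", "contributors",
        ],
    )
    return report, audit


# ---------------------------------------------------------------------------
# the full sweep (the summary-table engine)


def _scope_predictions(
    scope: str,
    protein_evidence: Sequence,
    category_evidence: Sequence,
    protein_map: EffectMapping,
    ipa_map: EffectMapping,
    threshold: EvidenceGrade,
) -> Tuple[PredictionSet, List[EffectMapping], Tuple[str, ...]]:
    """Predictions, active mappings and organs for one report scope."""
    kind, unit = scope.split(":")
    if kind == "protein":
        if unit == "combined":
            organs = ORGANS
            ev = protein_evidence
        else:
            organs = (CELL_LINE_ORGAN[unit],)
            ev = [e for e in protein_evidence if e.cell_line == unit]
        return map_predictions(ev, protein_map, threshold, organs), [protein_map], tuple(organs)
    if kind == "mRNA":
        if unit == "combined":
            organs = ORGANS
            ev = [e for e in category_evidence if e.input_scope == "combined"]
        else:
            input_scope = "liver_panel" if unit == "HepaRG" else "kidney_panel"
            organs = (CELL_LINE_ORGAN[unit],)
            ev = [e for e in category_evidence if e.input_scope == input_scope]
        return map_predictions(ev, ipa_map, threshold, organs), [ipa_map], tuple(organs)
    # combined:combined — OR over data types, both organs
    p_pred, _, _ = _scope_predictions(
        "protein:combined", protein_evidence, category_evidence, protein_map, ipa_map, threshold
    )
    m_pred, _, _ = _scope_predictions(
        "mRNA:combined", protein_evidence, category_evidence, protein_map, ipa_map, threshold
    )
    return combine_scopes([p_pred, m_pred]), [protein_map, ipa_map], ORGANS


def threshold_sweep(
    protein_evidence: Sequence,
    category_evidence: Sequence,
    protein_map: EffectMapping,
    ipa_map: EffectMapping,
    observed: InVivoProfile,
    substances: Optional[Sequence[str]] = None,
    scopes: Sequence[str] = SCOPES,
    thresholds: Sequence[EvidenceGrade] = SWEEP_THRESHOLDS,
    include_unmapped: bool = False,
) -> Tuple[List[ConcordanceReport], pd.DataFrame]:
    """One report per scope x threshold (21 rows for the full design)."""
    reports: List[ConcordanceReport] = []
    audits = []
    for scope in scopes:
        for threshold in thresholds:
            preds, mappings, organs = _scope_predictions(
                scope, protein_evidence, category_evidence, protein_map, ipa_map, threshold
            )
            report, audit = compute_concordance(
                preds,
                observed,
                mappings,
                scope=scope,
                threshold=threshold,
                organs=organs,
                substances=substances,
                include_unmapped=include_unmapped,
            )
            reports.append(report)
            audits.append(audit)
    audit_df = pd.concat(audits, ignore_index=True) if audits else pd.DataFrame()
    return reports, audit_df


def reports_to_frame(reports: Sequence[ConcordanceReport]) -> pd.DataFrame:
    """Long-format table of the sweep, raw ratios plus display rounding."""
    rows = []
    for r in reports:
        d = r.to_dict()
        d.update({f"display_{k}": v for k, v in r.rounded().items()})
        rows.append(d)
    return pd.DataFrame(rows)
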