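"""End-to-end pipeline driver.

Chains quantification, differential-expression summaries, annotation
grading, protein grading and the concordance sweep, and writes
machine-readable (CSV) and human-readable (JSON) reports.  The whole run is
a pure function of (inputs, config, seed): rerunning with the same bundle
and configuration produces byte-identical outputs, and only the bootstrap
p-values consume randomness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence

import pandas as pd

from . import io as tio
from .concordance import ConcordanceReport, EffectMapping, InVivoProfile, reports_to_frame, threshold_sweep
from .config import RunConfig
from .errors import StageError
from .pathways import PathwayCatalog, call_deg, pct_deg
from .protein import MarkerEvidence, evaluate_protein_panel, evidence_to_frame
from .qpcr import quantify
from .simulate import StudyBundle
from .transcript import (
    AnnotationRecord,
    CategoryEvidence,
    build_annotation_records,
    category_evidence_to_frame,
    evaluate_annotations,
    filter_ipa_input,
)

logger = logging.getLogger(__name__)

INPUT_SCOPE_OF = {"HepaRG": "liver_panel", "RPTEC": "kidney_panel"}


@dataclass
class PipelineResult:
    expression: pd.DataFrame
    deg_summary: pd.DataFrame
    marker_evidence: List[MarkerEvidence]
    category_evidence: List[CategoryEvidence]
    reports: List[ConcordanceReport]
    audit: pd.DataFrame

    def report_frame(self) -> pd.DataFrame:
        return reports_to_frame(self.reports)

    def report(self, scope: str, threshold) -> ConcordanceReport:
        from .grades import EvidenceGrade

        threshold = EvidenceGrade.parse(threshold)
        for r in self.reports:
            if r.scope == scope and r.threshold == threshold:
                return r
        raise KeyError((scope, threshold))

    def to_json(self) -> str:
        payload = {
            "concordance": [r.to_dict() for r in self.reports],
            "n_marker_evidence": len(self.marker_evidence),
            "n_category_evidence": len(self.category_evidence),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 — re-raise tagged
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("quantify")
def _quantify_all(
    ct_tables: Mapping[str, pd.DataFrame],
    housekeeping: Mapping[str, Sequence[str]],
    config: RunConfig,
) -> pd.DataFrame:
    logger.info("quantify: Ct cutoff %s", config.ct_cutoff)
    frames = [
        quantify(df, housekeeping[cl], ct_cutoff=config.ct_cutoff)
        for cl, df in sorted(ct_tables.items())
        if len(df)
    ]
    if not frames:
        from .qpcr import EXPRESSION_COLUMNS

        return pd.DataFrame(columns=EXPRESSION_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@_stage("deg_summary")
def _deg_summaries(
    expression: pd.DataFrame,
    catalogs: Mapping[str, PathwayCatalog],
    config: RunConfig,
) -> pd.DataFrame:
    logger.info(
        "deg_summary: |FR| >= %s and p < %s", config.fc_threshold, config.alpha
    )
    frames = []
    for (cell_line, substance), grp in expression.groupby(["cell_line", "substance"], sort=True):
        catalog = catalogs.get(cell_line)
        if catalog is None:
            continue
        deg = call_deg(grp, config.fc_threshold, config.alpha)
        summary = pct_deg(deg, catalog)
        summary.insert(0, "substance", substance)
        summary.insert(0, "cell_line", cell_line)
        frames.append(summary)
    if not frames:
        return pd.DataFrame(columns=["cell_line", "substance", "pathway", "n_genes", "n_deg", "pct_deg"])
    return pd.concat(frames, ignore_index=True)


def _merge_combined(expression: pd.DataFrame, priority: str = "HepaRG") -> pd.DataFrame:
    """Combined-panel expression: genes present on both arrays keep the
    liver-panel measurement."""
    order = expression["cell_line"].map(lambda cl: 0 if cl == priority else 1)
    merged = (
        expression.assign(_prio=order)
        .sort_values(["substance", "gene", "_prio"], kind="mergesort")
        .drop_duplicates(["substance", "gene"], keep="first")
        .drop(columns="_prio")
    )
    dropped = len(expression) - len(merged)
    if dropped:
        logger.info("combined panel: %d duplicate gene rows removed (kept %s)", dropped, priority)
    return merged.reset_index(drop=True)


@_stage("annotations")
def _annotation_records(
    expression: pd.DataFrame,
    category_sets: Mapping[str, Mapping[str, FrozenSet[str]]],
    backgrounds: Mapping[str, FrozenSet[str]],
    config: RunConfig,
) -> List[AnnotationRecord]:
    """Synthetic knowledge-base exports from the filtered expression table."""
    logger.info(
        "annotations: input filter |FR| >= %s, p <= %s", config.fr_cutoff, config.alpha
    )
    records: List[AnnotationRecord] = []
    cell_lines = sorted(category_sets)
    for substance, sub_expr in expression.groupby("substance", sort=True):
        merged_deg: set = set()
        merged_bg: set = set()
        merged_sets: Dict[str, set] = {}
        for cl in cell_lines:
            grp = sub_expr[sub_expr["cell_line"] == cl]
            bg = set(backgrounds[cl])
            deg = set(filter_ipa_input(grp, config.fr_cutoff, config.alpha)["gene"]) & bg
            records.extend(
                build_annotation_records(deg, category_sets[cl], bg, substance, INPUT_SCOPE_OF.get(cl, cl))
            )
            for cat, genes in category_sets[cl].items():
                merged_sets.setdefault(cat, set()).update(set(genes) & bg)
            merged_bg |= bg
        if len(cell_lines) > 1:
            combined_expr = _merge_combined(sub_expr)
            merged_deg = set(
                filter_ipa_input(combined_expr, config.fr_cutoff, config.alpha)["gene"]
            ) & merged_bg
            records.extend(
                build_annotation_records(merged_deg, merged_sets, merged_bg, substance, "combined")
            )
    return records


@_stage("transcript_grade")
def _transcript_grade(
    records: Sequence[AnnotationRecord],
    whitelist: FrozenSet[str],
    config: RunConfig,
) -> List[CategoryEvidence]:
    logger.info("transcript_grade: p-value grades %s", (config.ipa_p_grades,))
    return evaluate_annotations(
        records, whitelist, thresholds=config.ipa_p_grades, rule=config.collapse_rule
    )


@_stage("protein_grade")
def _protein_grade(panel: pd.DataFrame, config: RunConfig) -> List[MarkerEvidence]:
    logger.info("protein_grade: bands %s, n_boot %s", config.protein_grade_bounds, config.n_boot)
    return evaluate_protein_panel(
        panel,
        bounds=config.protein_grade_bounds,
        n_boot=config.n_boot,
        seed=config.rng_seed,
        method=config.bootstrap_method,
    )


@_stage("concordance")
def _concordance(
    marker_evidence,
    category_evidence,
    protein_map: EffectMapping,
    ipa_map: EffectMapping,
    observed: InVivoProfile,
    substances: Sequence[str],
    config: RunConfig,
):
    return threshold_sweep(
        marker_evidence,
        category_evidence,
        protein_map,
        ipa_map,
        observed,
        substances=substances,
        include_unmapped=config.include_unmapped_effects,
    )


def run_study(
    bundle: StudyBundle,
    config: Optional[RunConfig] = None,
    out_dir: Optional[Path] = None,
    annotation_records: Optional[Sequence[AnnotationRecord]] = None,
    protein_map: Optional[EffectMapping] = None,
    ipa_map: Optional[EffectMapping] = None,
    whitelist: Optional[FrozenSet[str]] = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory study bundle."""
    config = config or RunConfig()
    protein_map = protein_map or tio.load_ontology(kind="protein_map")
    ipa_map = ipa_map or tio.load_ontology(kind="category_map")

    housekeeping = {cl: p.housekeeping for cl, p in bundle.scenario.panels.items()}
    backgrounds = {cl: frozenset(p.targets) for cl, p in bundle.scenario.panels.items()}
    expression = _quantify_all(bundle.ct_tables, housekeeping, config)

    catalogs = {}
    for cl, sets in bundle.scenario.category_sets.items():
        usable = {c: frozenset(g) & backgrounds[cl] for c, g in sets.items()}
        usable = {c: g for c, g in usable.items() if g}
        if usable:
            catalogs[cl] = PathwayCatalog(sets=usable, background=backgrounds[cl])
    deg_summary = _deg_summaries(expression, catalogs, config)

    if annotation_records is None:
        annotation_records = _annotation_records(
            expression, bundle.scenario.category_sets, backgrounds, config
        )
    if whitelist is None:
        packaged = tio.load_category_whitelist()
        local = frozenset(
            c for sets in bundle.scenario.category_sets.values() for c in sets
        )
        whitelist = packaged | local
    category_evidence = _transcript_grade(annotation_records, whitelist, config)
    marker_evidence = _protein_grade(bundle.protein_panel, config)

    reports, audit = _concordance(
        marker_evidence,
        category_evidence,
        protein_map,
        ipa_map,
        bundle.observed,
        bundle.scenario.substances,
        config,
    )
    result = PipelineResult(
        expression=expression,
        deg_summary=deg_summary,
        marker_evidence=marker_evidence,
        category_evidence=category_evidence,
        reports=reports,
        audit=audit,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_table(result.expression, out / "expression.csv")
    tio.write_table(result.deg_summary, out / "deg_summary.csv")
    tio.write_table(evidence_to_frame(result.marker_evidence), out / "marker_evidence.csv")
    tio.write_table(
        category_evidence_to_frame(result.category_evidence), out / "category_evidence.csv"
    )
    tio.write_table(result.report_frame(), out / "concordance.csv")
    tio.write_table(result.audit, out / "concordance_audit.csv")
    (out / "report.json").write_text(result.to_json(), encoding="utf-8")
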