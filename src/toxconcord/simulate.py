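"""Synthetic study generator.

Emulates the statistical structure of a two-cell-line targeted
toxicogenomics study: long-format Ct tables from ~370-gene PCR arrays with
five housekeeping genes, an 8-marker protein panel measured on a
2 concentrations x 2 timepoints x 3 replicates grid, and an in vivo effect
registry drawn so that the expected pipeline concordance equals a chosen
target.

Noise models: Ct noise is Gaussian on the cycle scale (the standard qPCR
error model); protein noise is multiplicative lognormal with the geometric
mean at the condition's true percent-of-control, parameterized by a
coefficient of variation.  Everything is deterministic given the scenario
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from .concordance import (
    ORGANS,
    ConcordanceReport,
    EffectMapping,
    InVivoProfile,
    PredictionSet,
    _scope_predictions,
    compute_concordance,
)
from .grades import EvidenceGrade
from .pathways import fisher_overlap
from .protein import MARKER_FUNCTIONS, ConditionResult, MarkerEvidence, grade_protein
from .transcript import CategoryEvidence, grade_category

CELL_LINES = ("HepaRG", "RPTEC")

#: condition-mean templates per planted grade (percent of solvent control);
#: chosen well inside the 150/200 bands so moderate assay noise does not
#: change the planted call
GRADE_TEMPLATES = {
    EvidenceGrade.VERY_STRONG: (280.0, 260.0, 170.0, 120.0),
    EvidenceGrade.STRONG: (260.0, 130.0, 120.0, 110.0),
    EvidenceGrade.MEDIUM: (180.0, 125.0, 115.0, 105.0),
    EvidenceGrade.NONE: (100.0, 100.0, 100.0, 100.0),
}


@dataclass
class PanelSpec:
    cell_line: str
    targets: List[str]
    housekeeping: List[str]

    @property
    def genes(self) -> List[str]:
        return self.targets + self.housekeeping


@dataclass
class SimulationScenario:
    """Complete description of a synthetic study."""

    substances: List[str]
    panels: Dict[str, PanelSpec]
    #: cell_line -> category -> gene set (the knowledge-base stand-in)
    category_sets: Dict[str, Dict[str, FrozenSet[str]]]
    #: (cell_line, substance) -> gene -> true log2 fold change
    true_log2fc: Dict[Tuple[str, str], Dict[str, float]]
    #: (cell_line, substance, marker) -> per-condition true percent
    protein_truth: Dict[Tuple[str, str, str], Tuple[float, ...]]
    replicate_sd: float = 0.25
    n_replicates: int = 3
    protein_cv: float = 0.3
    #: substance -> (high concentration, low concentration) in uM
    concentrations: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    #: optional per-substance restriction of the measured target genes
    #: (housekeeping genes are always measured); used by calibration
    #: scenarios that need statistically independent null genes
    genes_by_substance: Dict[str, List[str]] = field(default_factory=dict)
    times: Tuple[float, float] = (36.0, 72.0)
    target_concordance: float = 0.75
    obs_rate_predicted: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be positive")
        if not (0.0 <= self.target_concordance <= 1.0):
            raise ValueError("target_concordance must be in [0, 1]")

    def conditions(self, substance: str) -> List[Tuple[float, float]]:
        high, low = self.concentrations.get(substance, (100.0, 33.0))
        return [(c, t) for c in (high, low) for t in self.times]


# ---------------------------------------------------------------------------
# scenario constructors


def null_scenario(
    n_genes: int = 500,
    n_replicates: int = 3,
    replicate_sd: float = 0.25,
    protein_cv: float = 0.3,
    seed: int = 0,
) -> SimulationScenario:
    """No true effects anywhere — for calibration checks.

    Each null gene is measured in its own independent exposure slice (own
    treated and control samples, own housekeeping noise).  Genes measured
    together share the housekeeping-mean term of their sample, which
    correlates their tests; one gene per slice keeps the null genes
    independent so the rejection fraction is binomial.
    """
    targets = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    hk = ["ACTB", "B2M", "GAPDH", "HPRT1", "RPLP0"]
    panel = PanelSpec("HepaRG", targets, hk)
    substances = [f"Null-{i:04d}" for i in range(1, n_genes + 1)]
    return SimulationScenario(
        substances=substances,
        panels={"HepaRG": panel},
        category_sets={"HepaRG": {}},
        true_log2fc={},
        protein_truth={
            ("HepaRG", substances[0], m): GRADE_TEMPLATES[EvidenceGrade.NONE]
            for m in MARKER_FUNCTIONS
        },
        replicate_sd=replicate_sd,
        n_replicates=n_replicates,
        protein_cv=protein_cv,
        concentrations={s: (100.0, 33.0) for s in substances},
        genes_by_substance=dict(zip(substances, ([g] for g in targets))),
        seed=seed,
    )


def study_scenario(
    seed: int = 0,
    n_substances: int = 6,
    target_concordance: float = 0.75,
    p_active: float = 0.3,
    protein_cv: float = 0.1,
    replicate_sd: float = 0.15,
    n_replicates: int = 3,
    panels: Optional[Dict[str, PanelSpec]] = None,
    category_sets: Optional[Dict[str, Dict[str, FrozenSet[str]]]] = None,
) -> SimulationScenario:
    """A study-shaped scenario with randomly planted in vitro activity.

    Per (cell line, substance): each protein marker is active with
    probability ``p_active`` at a random grade; each knowledge-base category
    is active with probability ``p_active``, in which case its gene set is
    planted with a true log2 fold change of 2.  Panels default to the
    packaged synthetic 370-gene manifests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    if panels is None:
        panels = {}
        for cl in CELL_LINES:
            manifest = tio.packaged_panel(cl)
            panels[cl] = PanelSpec(cl, manifest["targets"], manifest["housekeeping"])
    if category_sets is None:
        category_sets = {cl: dict(tio.packaged_catalog(cl)) for cl in panels}

    substances = [f"Substance-{i:02d}" for i in range(1, n_substances + 1)]
    active_grades = [EvidenceGrade.MEDIUM, EvidenceGrade.STRONG, EvidenceGrade.VERY_STRONG]

    protein_truth = {}
    for cl in panels:
        for sub in substances:
            for marker in MARKER_FUNCTIONS:
                if rng.random() < p_active:
                    grade = active_grades[rng.integers(0, len(active_grades))]
                else:
                    grade = EvidenceGrade.NONE
                protein_truth[(cl, sub, marker)] = GRADE_TEMPLATES[grade]

    true_log2fc: Dict[Tuple[str, str], Dict[str, float]] = {}
    for cl, sets in category_sets.items():
        for sub in substances:
            lfc: Dict[str, float] = {}
            for category in sorted(sets):
                if rng.random() < p_active:
                    # plant a varying fraction of the set so overlap p-values
                    # span the grade bands rather than all saturating
                    genes = sorted(sets[category])
                    frac = float(rng.choice([0.25, 0.5, 1.0]))
                    k = max(1, int(round(frac * len(genes))))
                    chosen = rng.choice(genes, size=k, replace=False)
                    for g in chosen:
                        lfc[g] = 2.0
            true_log2fc[(cl, sub)] = lfc

    concentrations = {
        sub: (float(c), round(0.33 * float(c), 4))
        for sub, c in zip(substances, rng.uniform(30, 900, size=len(substances)))
    }
    return SimulationScenario(
        substances=substances,
        panels=panels,
        category_sets=category_sets,
        true_log2fc=true_log2fc,
        protein_truth=protein_truth,
        replicate_sd=replicate_sd,
        n_replicates=n_replicates,
        protein_cv=protein_cv,
        concentrations=concentrations,
        target_concordance=target_concordance,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# data generation


def simulate_ct_table(scenario: SimulationScenario, cell_line: str) -> pd.DataFrame:
    """Long-format Ct table for one cell line.

    Housekeeping Cts have identical expectation in both groups; a target
    gene's treated expectation is its control baseline minus the planted
    log2 fold change (one extra cycle equals a halving of template).
    """
    panel = scenario.panels[cell_line]
    cl_idx = sorted(scenario.panels).index(cell_line)
    base_rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 11, cl_idx]))
    baselines = dict(
        zip(panel.targets, base_rng.uniform(22.0, 30.0, size=len(panel.targets)))
    )
    baselines.update({g: 20.0 for g in panel.housekeeping})

    n_rep = scenario.n_replicates
    rows = []
    for s_idx, substance in enumerate(scenario.substances):
        rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed, 12, cl_idx, s_idx])
        )
        targets = scenario.genes_by_substance.get(substance, panel.targets)
        genes = list(targets) + list(panel.housekeeping)
        base_vec = np.array([baselines[g] for g in genes])
        lfc = scenario.true_log2fc.get((cell_line, substance), {})
        shift = np.array([lfc.get(g, 0.0) for g in genes])
        high = scenario.concentrations.get(substance, (100.0, 33.0))[0]
        for group, expect in (
            ("treated", base_vec - shift),
            ("untreated_control", base_vec),
        ):
            noise = rng.normal(0.0, scenario.replicate_sd, size=(n_rep, len(genes)))
            cts = expect[None, :] + noise
            for r in range(n_rep):
                sample_id = f"{cell_line}_{substance}_{group}_r{r + 1}"
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": sample_id,
                            "cell_line": cell_line,
                            "substance": substance,
                            "concentration": high if group == "treated" else 0.0,
                            "time": 36.0,
                            "group": group,
                            "gene": genes,
                            "ct": cts[r],
                        }
                    )
                )
    if not rows:
        df = pd.DataFrame(columns=tio.CT_COLUMNS)
    else:
        df = pd.concat(rows, ignore_index=True)
    df["undetected"] = False
    df["is_housekeeping"] = df["gene"].isin(panel.housekeeping)
    return df


def simulate_protein_panel(scenario: SimulationScenario) -> pd.DataFrame:
    """Replicate protein measurements, lognormal around the condition truth."""
    sigma = float(np.sqrt(np.log(1.0 + scenario.protein_cv**2)))
    rows = []
    keys = sorted(scenario.protein_truth)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 21]))
    for cell_line, substance, marker in keys:
        truths = scenario.protein_truth[(cell_line, substance, marker)]
        conditions = scenario.conditions(substance)
        for (conc, time), truth in zip(conditions, truths):
            z = rng.standard_normal(scenario.n_replicates)
            values = truth * np.exp(sigma * z)
            for r, v in enumerate(values, start=1):
                rows.append(
                    {
                        "marker": marker,
                        "cell_line": cell_line,
                        "substance": substance,
                        "concentration": conc,
                        "time": time,
                        "replicate": r,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows, columns=tio.PROTEIN_COLUMNS)


# ---------------------------------------------------------------------------
# expected (noise-free) evidence from the planted truth


def expected_protein_evidence(scenario: SimulationScenario) -> List[MarkerEvidence]:
    out = []
    for (cell_line, substance, marker), truths in sorted(scenario.protein_truth.items()):
        conditions = [
            ConditionResult(c, t, m)
            for (c, t), m in zip(scenario.conditions(substance), truths)
        ]
        out.append(
            MarkerEvidence(
                substance=substance,
                cell_line=cell_line,
                cellular_function=MARKER_FUNCTIONS.get(marker, marker),
                grade=grade_protein(truths),
                conditions=conditions,
                marker=marker,
            )
        )
    return out


def _true_deg(scenario: SimulationScenario, cell_line: str, substance: str) -> FrozenSet[str]:
    lfc = scenario.true_log2fc.get((cell_line, substance), {})
    return frozenset(g for g, v in lfc.items() if abs(v) >= 1.0)


def expected_category_evidence(scenario: SimulationScenario) -> List[CategoryEvidence]:
    """Category grades implied by the planted fold changes, per input scope."""
    out = []
    cell_lines = sorted(scenario.panels)
    scope_of = {"HepaRG": "liver_panel", "RPTEC": "kidney_panel"}
    for substance in scenario.substances:
        merged_deg: set = set()
        merged_bg: set = set()
        merged_sets: Dict[str, set] = {}
        for cl in cell_lines:
            bg = frozenset(scenario.panels[cl].targets)
            deg = _true_deg(scenario, cl, substance) & bg
            merged_deg |= deg
            merged_bg |= bg
            for cat, genes in scenario.category_sets[cl].items():
                merged_sets.setdefault(cat, set()).update(set(genes) & bg)
            scope = scope_of.get(cl, cl)
            for cat in sorted(scenario.category_sets[cl]):
                genes = frozenset(scenario.category_sets[cl][cat]) & bg
                if not genes:
                    continue
                p = fisher_overlap(deg, genes, bg)
                out.append(
                    CategoryEvidence(substance, scope, cat, p, grade_category(p))
                )
        if len(cell_lines) > 1:
            for cat in sorted(merged_sets):
                genes = frozenset(merged_sets[cat])
                if not genes:
                    continue
                p = fisher_overlap(merged_deg, genes, frozenset(merged_bg))
                out.append(
                    CategoryEvidence(substance, "combined", cat, p, grade_category(p))
                )
    return out


# ---------------------------------------------------------------------------
# the full study


@dataclass
class GroundTruth:
    expected_protein_evidence: List[MarkerEvidence]
    expected_category_evidence: List[CategoryEvidence]
    expected_predictions: PredictionSet
    expected_report: ConcordanceReport
    target_concordance: float


@dataclass
class StudyBundle:
    scenario: SimulationScenario
    ct_tables: Dict[str, pd.DataFrame]
    protein_panel: pd.DataFrame
    observed: InVivoProfile
    truth: GroundTruth

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cl, df in self.ct_tables.items():
            tio.write_ct_table(df, out / f"ct_{cl}.csv")
        tio.write_table(self.protein_panel, out / "protein_panel.csv")
        tio.write_table(tio.in_vivo_to_frame(self.observed), out / "in_vivo_profiles.csv")
        for cl, sets in self.scenario.category_sets.items():
            rows = [
                {"panel": cl, "collection": "ipa_category", "pathway": c, "gene": g}
                for c in sorted(sets)
                for g in sorted(sets[c])
            ]
            tio.write_table(pd.DataFrame(rows), out / f"catalog_{cl}.csv")


def simulate_study(
    scenario: SimulationScenario,
    protein_map: Optional[EffectMapping] = None,
    ipa_map: Optional[EffectMapping] = None,
) -> StudyBundle:
    """Generate a pipeline-ready bundle plus its ground truth.

    The in vivo registry is drawn conditional on the planted in vitro
    predictions: a triple the (noise-free) pipeline would predict positive
    is observed positive with probability ``obs_rate_predicted``; the rate
    for unpredicted triples is set so that the expected indicative
    concordance at the "at least medium" threshold equals
    ``target_concordance``.
    """
    protein_map = protein_map or tio.load_ontology(kind="protein_map")
    ipa_map = ipa_map or tio.load_ontology(kind="category_map")

    prot_ev = expected_protein_evidence(scenario)
    cat_ev = expected_category_evidence(scenario)
    preds, mappings, organs = _scope_predictions(
        "combined:combined", prot_ev, cat_ev, protein_map, ipa_map, EvidenceGrade.MEDIUM
    )

    # evaluation universe of the combined scope
    triples = []
    for substance in scenario.substances:
        for organ in ORGANS:
            reachable = protein_map.reachable_effects(organ) | ipa_map.reachable_effects(organ)
            slot = preds.get((substance, organ), {})
            for effect in sorted(reachable):
                triples.append((substance, organ, effect, effect in slot))

    n_plus = sum(1 for t in triples if t[3])
    n_minus = len(triples) - n_plus
    a = scenario.obs_rate_predicted
    c = scenario.target_concordance
    if c <= 0 or n_plus == 0:
        b = a if n_minus else 0.0
        a = 0.0 if n_plus else a
    elif n_minus == 0:
        b = 0.0
    else:
        b = min(1.0, a * n_plus * (1.0 - c) / (c * n_minus))

    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 31]))
    effects: Dict[str, Dict[str, set]] = {}
    for substance, organ, effect, predicted in triples:
        p_obs = a if predicted else b
        if rng.random() < p_obs:
            effects.setdefault(substance, {}).setdefault(organ, set()).add(effect)
    observed = InVivoProfile(
        effects={
            s: {o: frozenset(v) for o, v in orgs.items()} for s, orgs in effects.items()
        }
    )

    expected_report, _ = compute_concordance(
        preds,
        observed,
        [protein_map, ipa_map],
        scope="combined:combined",
        threshold=EvidenceGrade.MEDIUM,
        organs=ORGANS,
        substances=scenario.substances,
    )

    ct_tables = {cl: simulate_ct_table(scenario, cl) for cl in sorted(scenario.panels)}
    protein_panel = simulate_protein_panel(scenario)
    truth = GroundTruth(
        expected_protein_evidence=prot_ev,
        expected_category_evidence=cat_ev,
        expected_predictions=preds,
        expected_report=expected_report,
        target_concordance=scenario.target_concordance,
    )
    return StudyBundle(
        scenario=scenario,
        ct_tables=ct_tables,
        protein_panel=protein_panel,
        observed=observed,
        truth=truth,
    )
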