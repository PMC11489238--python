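import numpy as np
import pandas as pd
import pytest

from toxconcord.concordance import (
    ORGANS,
    SCOPES,
    EffectMapping,
    InVivoProfile,
    MappingRule,
    combine_scopes,
    compute_concordance,
    map_predictions,
    reports_to_frame,
    threshold_sweep,
)
from toxconcord.grades import SWEEP_THRESHOLDS, EvidenceGrade
from toxconcord.protein import ConditionResult, MarkerEvidence
from toxconcord.transcript import CategoryEvidence

G = EvidenceGrade


def marker_ev(function, grade, cell_line="HepaRG", substance="X"):
    return MarkerEvidence(substance, cell_line, function, G(grade),
                          [ConditionResult(100.0, 36.0, 180.0)])


def cat_ev(category, grade, scope="liver_panel", substance="X"):
    p = {G.NONE: 0.5, G.MEDIUM: 0.02, G.STRONG: 0.002, G.VERY_STRONG: 0.0002}[G(grade)]
    return CategoryEvidence(substance, scope, category, p, G(grade))


def random_inputs(rng, protein_map, ipa_map, vocab_by_organ, n_substances=4):
    """Random graded evidence plus a random in vivo registry."""
    substances = [f"R{i:02d}" for i in range(n_substances)]
    functions = sorted(protein_map.endpoints())
    categories = sorted(ipa_map.endpoints())
    prot, cats = [], []
    for sub in substances:
        for cl in ("HepaRG", "RPTEC"):
            for fn in functions:
                prot.append(marker_ev(fn, int(rng.integers(0, 4)), cl, sub))
        for scope in ("liver_panel", "kidney_panel", "combined"):
            for c in categories:
                cats.append(cat_ev(c, int(rng.integers(0, 4)), scope, sub))
    effects = {}
    for sub in substances:
        effects[sub] = {
            organ: frozenset(
                e for e in vocab_by_organ[organ] if rng.random() < 0.4
            )
            for organ in ORGANS
        }
    return prot, cats, InVivoProfile(effects=effects), substances


def check_sweep_properties(prot, cats, observed, subs, protein_map, ipa_map):
    """Threshold monotonicity, universe conservation and OR-dominance.

    OR-dominance is evaluated on the constituent scope's own universe: the
    combined scope adds effects only the other data type can express, so
    comparing raw percentages across different denominators is not a valid
    invariant; on a shared universe the union of predictors can only add
    hits.
    """
    from toxconcord.concordance import _scope_predictions

    reports, _ = threshold_sweep(prot, cats, protein_map, ipa_map, observed, substances=subs)
    by = {(r.scope, r.threshold): r for r in reports}
    for scope in SCOPES:
        seq = [by[(scope, t)] for t in SWEEP_THRESHOLDS]
        # conservation of the universe across thresholds
        assert len({(r.n_pos + r.n_neg) for r in seq}) == 1
        for a, b in zip(seq, seq[1:]):
            if a.indicative_concordance is not None:
                assert b.indicative_concordance <= a.indicative_concordance + 1e-9
            if a.negative_agreement is not None:
                assert b.negative_agreement >= a.negative_agreement - 1e-9
    # only genuine OR-combinations: the merged-input mRNA scope is a
    # different analysis (merged gene list), not a union of the single-panel
    # scopes, so no dominance is implied there
    constituents = {
        "combined:combined": [("protein:combined", None), ("mRNA:combined", None)],
        "protein:combined": [("protein:HepaRG", ("liver",)), ("protein:RPTEC", ("kidney",))],
    }
    for combo, parts in constituents.items():
        for t in SWEEP_THRESHOLDS:
            combo_preds, _, _ = _scope_predictions(combo, prot, cats, protein_map, ipa_map, t)
            for part, organs in parts:
                part_report = by[(part, t)]
                _, part_mappings, part_organs = _scope_predictions(
                    part, prot, cats, protein_map, ipa_map, t
                )
                restricted, _ = compute_concordance(
                    combo_preds, observed, part_mappings,
                    organs=organs or part_organs, substances=subs,
                )
                assert restricted.n_pos == part_report.n_pos
                assert restricted.n_hit >= part_report.n_hit
    return reports


@pytest.fixture(scope="module")
def vocab_by_organ(protein_map, ipa_map):
    return {
        organ: sorted(protein_map.reachable_effects(organ) | ipa_map.reachable_effects(organ))
        for organ in ORGANS
    }


class TestMapPredictions:
    def test_translation_maps_to_three_liver_effects(self, protein_map):
        preds = map_predictions(
            [marker_ev("Translation", G.STRONG)], protein_map, G.MEDIUM, organs=("liver",)
        )
        assert set(preds[("X", "liver")]) == {
            "Neoplasms", "Foci of cellular alteration in the liver", "Hypertrophy",
        }

    def test_endpoint_without_targets_predicts_nothing(self, protein_map):
        preds = map_predictions(
            [marker_ev("Hypoxia", G.VERY_STRONG)], protein_map, G.MEDIUM
        )
        assert preds == {}

    def test_below_threshold_is_silent(self, ipa_map):
        preds = map_predictions(
            [cat_ev("Liver Steatosis", G.MEDIUM)], ipa_map, G.STRONG, organs=("liver",)
        )
        assert preds == {}

    def test_combination_rule_requires_all_members(self, ipa_map):
        both = [
            cat_ev("Liver Cholestasis", G.STRONG),
            cat_ev("Liver Inflammation/Hepatitis", G.MEDIUM),
        ]
        preds = map_predictions(both, ipa_map, G.MEDIUM, organs=("liver",))
        # the pair rule fires (both >= medium) at the weakest member's grade
        grade, src = preds[("X", "liver")]["Cholestasis"]
        assert "Liver Inflammation/Hepatitis" in src or grade >= G.MEDIUM
        only_one = map_predictions(
            [cat_ev("Liver Cholestasis", G.STRONG)], ipa_map, G.MEDIUM, organs=("liver",)
        )
        # single-member cholestasis row still fires on its own
        assert "Cholestasis" in only_one[("X", "liver")]
        # but the combination's inflammation target needs both members
        assert "Inflammation in the liver" not in only_one[("X", "liver")]


class TestCombineScopes:
    def test_union_and_idempotence(self):
        a = {("X", "liver"): {"Neoplasms": (G.MEDIUM, ("Translation",))}}
        b = {("X", "liver"): {"Cholestasis": (G.STRONG, ("Liver Cholestasis",))}}
        merged = combine_scopes([a, b])
        assert set(merged[("X", "liver")]) == {"Neoplasms", "Cholestasis"}
        assert combine_scopes([a, a]) == a
        assert combine_scopes([{}, {}]) == {}

    def test_best_grade_wins(self):
        a = {("X", "liver"): {"Neoplasms": (G.MEDIUM, ("Translation",))}}
        b = {("X", "liver"): {"Neoplasms": (G.VERY_STRONG, ("Cell division",))}}
        grade, src = combine_scopes([a, b])[("X", "liver")]["Neoplasms"]
        assert grade is G.VERY_STRONG
        assert set(src) == {"Translation", "Cell division"}


class TestComputeConcordance:
    def _mapping(self):
        return EffectMapping("protein", [
            MappingRule(("Apoptosis",), "liver",
                        frozenset({"Hepatocellular cell degeneration/death"})),
            MappingRule(("Translation",), "liver", frozenset({"Neoplasms", "Hypertrophy"})),
        ])

    def test_two_of_three_positives_hit(self):
        mapping = self._mapping()
        observed = InVivoProfile(effects={"X": {"liver": frozenset(
            {"Hepatocellular cell degeneration/death", "Neoplasms", "Hypertrophy"}
        )}})
        preds = {("X", "liver"): {
            "Neoplasms": (G.MEDIUM, ("Translation",)),
            "Hypertrophy": (G.MEDIUM, ("Translation",)),
        }}
        report, audit = compute_concordance(preds, observed, mapping, organs=("liver",))
        assert (report.n_pos, report.n_hit) == (3, 2)
        assert report.indicative_concordance == pytest.approx(66.667, abs=0.01)
        assert len(audit) == 3

    def test_no_predictions_scores_zero_and_full_negative_agreement(self):
        mapping = self._mapping()
        observed = InVivoProfile(effects={"X": {"liver": frozenset({"Neoplasms"})}})
        report, _ = compute_concordance({}, observed, mapping, organs=("liver",))
        assert report.indicative_concordance == 0.0
        assert report.negative_agreement == 100.0

    def test_empty_universe_warns_and_yields_null(self, caplog):
        mapping = EffectMapping("protein", [])
        observed = InVivoProfile(effects={"X": {"liver": frozenset()}})
        with caplog.at_level("WARNING"):
            report, audit = compute_concordance({}, observed, mapping, organs=("liver",))
        assert report.indicative_concordance is None
        assert report.negative_agreement is None
        assert audit.empty
        assert any("empty evaluation universe" in r.message for r in caplog.records)

    def test_removing_mapping_targets_shrinks_both_sides(self):
        """Dropping a target removes its triples from numerator and
        denominator rather than scoring them as misses."""
        full = self._mapping()
        reduced = EffectMapping("protein", [full.rules[1]])
        observed = InVivoProfile(effects={"X": {"liver": frozenset(
            {"Hepatocellular cell degeneration/death", "Neoplasms"}
        )}})
        preds = {("X", "liver"): {"Neoplasms": (G.MEDIUM, ("Translation",))}}
        r_full, _ = compute_concordance(preds, observed, full, organs=("liver",))
        r_red, _ = compute_concordance(preds, observed, reduced, organs=("liver",))
        assert r_full.n_pos == 2 and r_red.n_pos == 1
        assert r_red.indicative_concordance == pytest.approx(100.0)

    def test_include_unmapped_counts_misses(self):
        mapping = self._mapping()
        observed = InVivoProfile(effects={"X": {"liver": frozenset({"Calculi"})}})
        r_excl, _ = compute_concordance({}, observed, mapping, organs=("liver",))
        r_incl, _ = compute_concordance(
            {}, observed, mapping, organs=("liver",), include_unmapped=True
        )
        assert r_excl.n_pos == 0
        assert r_incl.n_pos == 1 and r_incl.n_hit == 0


class TestSweepProperties:
    def test_all_none_evidence_gives_zero_everywhere(self, protein_map, ipa_map, in_vivo):
        prot = [marker_ev(fn, G.NONE, cl, "Chlorotoluron")
                for fn in sorted(protein_map.endpoints()) for cl in ("HepaRG", "RPTEC")]
        reports, _ = threshold_sweep(prot, [], protein_map, ipa_map, in_vivo,
                                     substances=["Chlorotoluron"])
        assert len(reports) == 21
        for r in reports:
            assert r.n_hit == 0
            if r.n_neg:
                assert r.negative_agreement == 100.0

    def test_monotonicity_and_or_dominance_random(self, protein_map, ipa_map, vocab_by_organ):
        rng = np.random.default_rng(12345)
        for _ in range(20):
            prot, cats, observed, subs = random_inputs(rng, protein_map, ipa_map, vocab_by_organ)
            check_sweep_properties(prot, cats, observed, subs, protein_map, ipa_map)

    def test_report_frame_shape(self, protein_map, ipa_map, in_vivo):
        reports, audit = threshold_sweep([], [], protein_map, ipa_map, in_vivo)
        frame = reports_to_frame(reports)
        assert len(frame) == 21
        assert {"scope", "threshold", "indicative_concordance", "display_indicative_concordance"} <= set(frame.columns)
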