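import numpy as np
import pandas as pd
import pytest

from toxconcord.config import RunConfig
from toxconcord.grades import EvidenceGrade
from toxconcord.pathways import call_deg
from toxconcord.protein import bootstrap_test, evaluate_protein_panel
from toxconcord.qpcr import quantify
from toxconcord.simulate import (
    GRADE_TEMPLATES,
    SimulationScenario,
    StudyBundle,
    expected_protein_evidence,
    null_scenario,
    simulate_ct_table,
    simulate_protein_panel,
    simulate_study,
    study_scenario,
)

from conftest import small_panels


def small_study(seed, **kw):
    panels, category_sets = small_panels()
    kw.setdefault("n_substances", 4)
    return study_scenario(seed=seed, panels=panels, category_sets=category_sets, **kw)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        sc = small_study(5)
        a = simulate_ct_table(sc, "HepaRG")
        b = simulate_ct_table(sc, "HepaRG")
        pd.testing.assert_frame_equal(a, b)
        pa = simulate_protein_panel(sc)
        pb = simulate_protein_panel(sc)
        pd.testing.assert_frame_equal(pa, pb)

    def test_different_seed_differs(self):
        a = simulate_ct_table(small_study(5), "HepaRG")
        b = simulate_ct_table(small_study(6), "HepaRG")
        assert not np.allclose(a["ct"], b["ct"])

    def test_study_bundle_deterministic(self):
        b1 = simulate_study(small_study(9))
        b2 = simulate_study(small_study(9))
        assert b1.observed.effects == b2.observed.effects
        pd.testing.assert_frame_equal(b1.protein_panel, b2.protein_panel)


class TestCtGeneration:
    def test_planted_shift_recovered_in_low_noise_limit(self):
        panels, cats = small_panels()
        sc = SimulationScenario(
            substances=["S"], panels={"HepaRG": panels["HepaRG"]},
            category_sets={"HepaRG": {}},
            true_log2fc={("HepaRG", "S"): {"LIV001": 1.0}},
            protein_truth={}, replicate_sd=1e-6, seed=0,
        )
        ct = simulate_ct_table(sc, "HepaRG")
        expr = quantify(ct, panels["HepaRG"].housekeeping).set_index("gene")
        assert expr.loc["LIV001", "fold_change"] == pytest.approx(2.0, rel=1e-3)

    def test_null_deg_fraction_near_zero(self):
        sc = null_scenario(n_genes=500, seed=3)
        ct = simulate_ct_table(sc, "HepaRG")
        expr = quantify(ct, sc.panels["HepaRG"].housekeeping)
        deg = call_deg(expr, fc_threshold=2.0, alpha=0.05)
        assert len(deg) / 500 < 0.01

    def test_log2fc_parameter_recovery(self):
        """Mean recovered log2 fold change across 200 planted genes within
        +-0.1 of the truth at replicate SD 0.25, n = 3."""
        hk = ["ACTB", "B2M", "GAPDH", "HPRT1", "RPLP0"]
        targets = [f"T{i:03d}" for i in range(200)]
        truth = 1.5
        from toxconcord.simulate import PanelSpec

        sc = SimulationScenario(
            substances=["S"], panels={"HepaRG": PanelSpec("HepaRG", targets, hk)},
            category_sets={"HepaRG": {}},
            true_log2fc={("HepaRG", "S"): {g: truth for g in targets}},
            protein_truth={}, replicate_sd=0.25, n_replicates=3, seed=11,
        )
        ct = simulate_ct_table(sc, "HepaRG")
        expr = quantify(ct, hk)
        est = -expr["mean_ddct"].mean()
        assert est == pytest.approx(truth, abs=0.1)


class TestProteinGeneration:
    def test_grade_recovery_in_low_cv_limit(self):
        panels, _ = small_panels()
        truths = {
            ("HepaRG", "S", "cleaved PARP"): GRADE_TEMPLATES[EvidenceGrade.VERY_STRONG],
            ("HepaRG", "S", "HSP70"): GRADE_TEMPLATES[EvidenceGrade.NONE],
        }
        sc = SimulationScenario(
            substances=["S"], panels={"HepaRG": panels["HepaRG"]},
            category_sets={"HepaRG": {}}, true_log2fc={},
            protein_truth=truths, protein_cv=0.01, seed=2,
        )
        panel = simulate_protein_panel(sc)
        evidence = evaluate_protein_panel(panel, n_boot=1000, seed=2)
        grades = {e.marker: e.grade for e in evidence}
        assert grades["cleaved PARP"] is EvidenceGrade.VERY_STRONG
        assert grades["HSP70"] is EvidenceGrade.NONE

    def test_high_variability_loses_power(self):
        """At equal truth, cv 0.6 flags fewer conditions significant than
        cv 0.1."""
        panels, _ = small_panels()
        truths = {("HepaRG", "S", m): (180.0, 180.0, 180.0, 180.0)
                  for m in ("cleaved PARP", "HSP70", "total LC3B", "p-elF4B")}

        def n_significant(cv, seed):
            sc = SimulationScenario(
                substances=["S"], panels={"HepaRG": panels["HepaRG"]},
                category_sets={"HepaRG": {}}, true_log2fc={},
                protein_truth=truths, protein_cv=cv, seed=seed,
            )
            panel = simulate_protein_panel(sc)
            evidence = evaluate_protein_panel(panel, n_boot=1000, seed=seed)
            return sum(
                c.bootstrap_p < 0.05 for e in evidence for c in e.conditions
            )

        low = sum(n_significant(0.1, s) for s in range(5))
        high = sum(n_significant(0.6, s) for s in range(5))
        assert high < low


class TestSimulateStudy:
    def test_perfect_limit_gives_full_concordance(self):
        sc = small_study(7, target_concordance=1.0, protein_cv=0.02, replicate_sd=0.02)
        sc.obs_rate_predicted = 1.0
        bundle = simulate_study(sc)
        r = bundle.truth.expected_report
        assert r.indicative_concordance == pytest.approx(100.0)
        assert r.negative_agreement == pytest.approx(100.0)

    def test_emptied_mapping_yields_null_report(self, caplog):
        from toxconcord.concordance import EffectMapping

        sc = small_study(8)
        empty = EffectMapping("protein", [])
        empty_cat = EffectMapping("category", [])
        with caplog.at_level("WARNING"):
            bundle = simulate_study(sc, protein_map=empty, ipa_map=empty_cat)
        assert bundle.truth.expected_report.indicative_concordance is None
        assert any("empty evaluation universe" in r.message for r in caplog.records)

    def test_bundle_is_pipeline_ready(self, tmp_path):
        bundle = simulate_study(small_study(10))
        bundle.write(tmp_path)
        assert (tmp_path / "ct_HepaRG.csv").exists()
        assert (tmp_path / "protein_panel.csv").exists()
        assert (tmp_path / "in_vivo_profiles.csv").exists()

    def test_expected_evidence_matches_planted_truth(self):
        sc = small_study(12)
        evidence = expected_protein_evidence(sc)
        for ev in evidence:
            truths = sc.protein_truth[(ev.cell_line, ev.substance, ev.marker)]
            from toxconcord.protein import grade_protein

            assert ev.grade is grade_protein(truths)
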