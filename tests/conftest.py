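import numpy as np
import pandas as pd
import pytest

from toxconcord import load_ontology
from toxconcord.simulate import PanelSpec, SimulationScenario


@pytest.fixture(scope="session")
def protein_map():
    return load_ontology(kind="protein_map")


@pytest.fixture(scope="session")
def ipa_map():
    return load_ontology(kind="category_map")


@pytest.fixture(scope="session")
def in_vivo():
    return load_ontology(kind="in_vivo")


def small_panels(n_sets: int = 4, set_size: int = 8, n_extra: int = 8):
    """Compact two-cell-line panels with disjoint category gene sets."""
    hk = ["ACTB", "B2M", "GAPDH", "HPRT1", "RPLP0"]
    panels, category_sets = {}, {}
    cats = {
        "HepaRG": ["Liver Steatosis", "Liver Inflammation/Hepatitis",
                   "Liver Necrosis/Cell Death", "Liver Proliferation"],
        "RPTEC": ["Renal Inflammation", "Renal Nephritis",
                  "Renal Necrosis/Cell Death", "Renal Proliferation"],
    }
    for cl, prefix in (("HepaRG", "LIV"), ("RPTEC", "KID")):
        n_genes = n_sets * set_size + n_extra
        targets = [f"{prefix}{i:03d}" for i in range(1, n_genes + 1)]
        panels[cl] = PanelSpec(cl, targets, hk)
        category_sets[cl] = {
            cats[cl][i]: frozenset(targets[i * set_size:(i + 1) * set_size])
            for i in range(n_sets)
        }
    return panels, category_sets


@pytest.fixture()
def small_panel_pair():
    return small_panels()


def make_ct_table(gene_cts: dict, hk_cts: dict, substance="X", cell_line="HepaRG",
                  n_rep=3, group_pairs=(("treated", 0.0), ("untreated_control", 0.0))):
    """Deterministic long-format Ct table: gene -> Ct per group offset."""
    rows = []
    for group, offset in group_pairs:
        for r in range(1, n_rep + 1):
            sid = f"{cell_line}_{substance}_{group}_r{r}"
            for gene, ct in {**gene_cts, **hk_cts}.items():
                shift = offset if gene in gene_cts else 0.0
                rows.append({
                    "sample_id": sid, "cell_line": cell_line, "substance": substance,
                    "concentration": 100.0, "time": 36.0, "group": group,
                    "gene": gene, "ct": ct + shift,
                })
    df = pd.DataFrame(rows)
    df["undetected"] = False
    df["is_housekeeping"] = df["gene"].isin(hk_cts)
    return df
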