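"""Grading of the 8-marker protein panel and bootstrap significance.

Each marker reports a cellular function (translation, transcription, protein
degradation, cell division, oxidative/heat stress, apoptosis, autophagy,
hypoxia) and is measured as percent of the solvent control on a grid of
conditions — two concentrations x two incubation times, three biological
replicates each.  Evidence is graded from the condition MEANS alone:

* very strong — at least 2 conditions above 200%
* strong      — 1 condition above 200%, or at least 2 in (150, 200]
* medium      — 1 condition in (150, 200]
* none        — otherwise

Only increases count: every analyte in the panel reads out an induction, so
values below the control never contribute a grade.  Bootstrap significance
against the 100% null is reported alongside each condition but does not gate
the grade.

The default significance method is a studentized parametric bootstrap on the
log scale: replicate noise on percent-of-control data is multiplicative, so
log-values are modelled as Gaussian around log(null) under H0 and the
studentized mean is simulated under that null.  The statistic is pivotal,
which keeps the test calibrated even at n = 3, where resampling three raw
values cannot resolve tail probabilities near 0.05.  The plain percentile
bootstrap of the mean is available as ``method="percentile"`` for
comparison; it is strongly anti-conservative at such sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .grades import EvidenceGrade

logger = logging.getLogger(__name__)

#: the panel's analytes and the cellular function each reads out
MARKER_FUNCTIONS = {
    "p-elF4B": "Translation",
    "p-RNA pol II": "Transcription",
    "Ubiquitin k48": "Protein degradation",
    "p-Histone H3": "Cell division",
    "HSP70": "Oxidative/heat stress",
    "cleaved PARP": "Apoptosis",
    "total LC3B": "Autophagy",
    "HIF 1-alpha": "Hypoxia",
}


def bootstrap_test(
    replicates: Sequence[float],
    null_value: float = 100.0,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "studentized",
) -> float:
    """Two-sided bootstrap p-value for the displacement from ``null_value``.

    Deterministic given ``seed``; invariant to replicate order.
    """
    x = np.asarray(list(replicates), dtype=float)
    if len(x) < 3:
        raise MissingDataError("bootstrap_test needs at least 3 replicates")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    if np.allclose(x, null_value):
        return 1.0
    rng = np.random.default_rng(seed)

    if method == "percentile":
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        means = x[idx].mean(axis=1)
        lo = float((means < null_value).mean())
        hi = float((means > null_value).mean())
        return min(1.0, 2.0 * min(lo, hi))

    if method != "studentized":
        raise ValueError(f"unknown bootstrap method {method!r}")
    if np.any(x <= 0) or null_value <= 0:
        raise ValueError("studentized log-scale bootstrap needs positive values")
    lx = np.log(x)
    s = lx.std(ddof=1)
    if np.isclose(s, 0.0):
        # identical replicates displaced from the null: maximal evidence
        return 1.0 / (n_boot + 1)
    n = len(x)
    t_obs = (lx.mean() - np.log(null_value)) / (s / np.sqrt(n))
    # the studentized mean is pivotal under the lognormal null, so the
    # parametric bootstrap may simulate from the standard normal directly
    z = rng.standard_normal(size=(n_boot, n))
    t_star = z.mean(axis=1) / (z.std(axis=1, ddof=1) / np.sqrt(n))
    p = (1.0 + np.count_nonzero(np.abs(t_star) >= abs(t_obs))) / (n_boot + 1.0)
    return float(min(1.0, p))


def grade_protein(
    condition_means: Sequence[float], bounds: Tuple[float, float] = (150.0, 200.0)
) -> EvidenceGrade:
    """Apply the evidence matrix to a marker's condition means.

    The middle band is the half-open interval (lower, upper]; the top band is
    strictly above the upper bound, so the bands partition.
    """
    lower, upper = bounds
    means = list(condition_means)
    if not 1 <= len(means):
        raise MissingDataError("grade_protein needs at least one condition mean")
    n_top = sum(m > upper for m in means)
    n_mid = sum(lower < m <= upper for m in means)
    for m in means:
        if m in (lower, upper):
            logger.info("grade_protein: condition mean exactly at band boundary (%s)", m)
    if n_top >= 2:
        return EvidenceGrade.VERY_STRONG
    if n_top >= 1 or n_mid >= 2:
        return EvidenceGrade.STRONG
    if n_mid >= 1:
        return EvidenceGrade.MEDIUM
    return EvidenceGrade.NONE


@dataclass(frozen=True)
class ConditionResult:
    concentration: float
    time: float
    mean: float
    bootstrap_p: Optional[float] = None


@dataclass
class MarkerEvidence:
    """Graded in vitro evidence for one cellular function in one cell line."""

    substance: str
    cell_line: str
    cellular_function: str
    grade: EvidenceGrade
    conditions: List[ConditionResult] = field(default_factory=list)
    marker: str = ""


def combine_cell_lines(a: MarkerEvidence, b: MarkerEvidence) -> MarkerEvidence:
    """OR-combination across cell lines: the better grade wins.

    Commutative, associative and idempotent; supporting conditions are
    concatenated (deduplicated) for the audit trail.
    """
    if a.substance != b.substance or a.cellular_function != b.cellular_function:
        raise ValueError("can only combine evidence for the same substance and function")
    conditions = list(dict.fromkeys([*a.conditions, *b.conditions]))
    return MarkerEvidence(
        substance=a.substance,
        cell_line="combined" if a.cell_line != b.cell_line else a.cell_line,
        cellular_function=a.cellular_function,
        grade=max(EvidenceGrade(a.grade), EvidenceGrade(b.grade)),
        conditions=conditions,
        marker=a.marker or b.marker,
    )


def evaluate_protein_panel(
    panel: pd.DataFrame,
    bounds: Tuple[float, float] = (150.0, 200.0),
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "studentized",
    marker_functions: Optional[Mapping[str, str]] = None,
) -> List[MarkerEvidence]:
    """Grade every (substance, cell line, marker) of a long-format panel.

    ``panel`` columns: marker, cell_line, substance, concentration, time,
    replicate, value (percent of solvent control).  Bootstrap seeds are
    derived deterministically from ``seed`` and the sorted group order.
    """
    functions = dict(marker_functions or MARKER_FUNCTIONS)
    out: List[MarkerEvidence] = []
    grouped = panel.groupby(["substance", "cell_line", "marker"], sort=True)
    for gi, ((substance, cell_line, marker), grp) in enumerate(grouped):
        conditions = []
        means = []
        cond_groups = grp.groupby(["concentration", "time"], sort=True)
        for ci, ((conc, time), rows) in enumerate(cond_groups):
            values = rows["value"].to_numpy(float)
            mean = float(values.mean())
            p = None
            if len(values) >= 3:
                child_seed = int(
                    np.random.SeedSequence([seed, gi, ci]).generate_state(1)[0] % (2**31)
                )
                p = bootstrap_test(values, 100.0, n_boot=n_boot, seed=child_seed, method=method)
            conditions.append(ConditionResult(float(conc), float(time), mean, p))
            means.append(mean)
        out.append(
            MarkerEvidence(
                substance=substance,
                cell_line=cell_line,
                cellular_function=functions.get(marker, marker),
                grade=grade_protein(means, bounds),
                conditions=conditions,
                marker=marker,
            )
        )
    return out


def combine_panel_evidence(evidence: Iterable[MarkerEvidence]) -> List[MarkerEvidence]:
    """Collapse per-cell-line evidence to one combined row per
    (substance, cellular function)."""
    by_key: Dict[Tuple[str, str], MarkerEvidence] = {}
    for ev in evidence:
        key = (ev.substance, ev.cellular_function)
        by_key[key] = combine_cell_lines(by_key[key], ev) if key in by_key else ev
    return [by_key[k] for k in sorted(by_key)]


def evidence_to_frame(evidence: Sequence[MarkerEvidence]) -> pd.DataFrame:
    rows = []
    for ev in evidence:
        rows.append(
            {
                "substance": ev.substance,
                "cell_line": ev.cell_line,
                "cellular_function": ev.cellular_function,
                "marker": ev.marker,
                "grade": ev.grade.name,
                "conditions": ";".join(
                    f"{c.concentration:g}uM/{c.time:g}h={c.mean:.1f}%"
                    + (f"(p={c.bootstrap_p:.4f})" if c.bootstrap_p is not None else "")
                    for c in ev.conditions
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["substance", "cell_line", "cellular_function", "marker", "grade", "conditions"],
    )
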