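"""Relative quantification of targeted qPCR arrays (the 2^-ddCt chain).

Threshold cycles are censored at a cutoff (35 cycles by default; later
cycles, and wells with no amplification, carry no reliable quantity).  Each
sample's target Cts are normalized to the arithmetic mean of its
housekeeping genes (dCt), treated and control samples are differenced
(ddCt), and relative expression is 2^-ddCt.  Fold regulation re-expresses a
fold change below 1 as its negative inverse so that up- and down-regulation
are symmetric around +-1.

Significance is a one-sample two-sided t-test of the per-replicate ddCt
values against 0, on the log2 (cycle) scale.  Replicates are paired by
position: biological replicate i of the treated group against biological
replicate i of the control group, each independent experiment carrying its
own control.  With unequal replicate counts the test falls back to a Welch
two-sample comparison of the dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, MissingDataError, NormalizationError


class CensoredCt(NamedTuple):
    value: float
    censored: bool


def censor_ct(ct: Optional[float], cutoff: float = 35.0) -> CensoredCt:
    """Clamp a threshold cycle at the detection cutoff.

    Undetected wells (``None``/NaN) and cycles above the cutoff are replaced
    by the cutoff and flagged censored.
    """
    if ct is None or (isinstance(ct, float) and np.isnan(ct)):
        return CensoredCt(cutoff, True)
    if ct > cutoff:
        return CensoredCt(cutoff, True)
    return CensoredCt(float(ct), False)


def delta_ct(sample: pd.DataFrame, reference_genes: Iterable[str]) -> pd.Series:
    """Housekeeping-normalized Cts for one sample.

    ``sample`` holds columns ``gene`` and ``ct`` for a single sample_id.
    dCt(gene) = Ct(gene) - mean(Ct of reference genes).
    """
    reference_genes = list(reference_genes)
    cts = sample.set_index("gene")["ct"]
    missing = [g for g in reference_genes if g not in cts.index or pd.isna(cts.get(g))]
    if missing:
        sid = sample["sample_id"].iloc[0] if "sample_id" in sample else "?"
        raise NormalizationError(
            f"reference gene(s) {missing} absent or undetected in sample {sid!r}"
        )
    hk_mean = float(cts.loc[reference_genes].mean())
    return cts - hk_mean


def fold_regulation(fold_change: float) -> float:
    """Signed fold representation: FC if >= 1, else -1/FC."""
    if fold_change <= 0:
        raise DomainError(f"fold change must be positive, got {fold_change}")
    if fold_change >= 1:
        return float(fold_change)
    return -1.0 / float(fold_change)


@dataclass
class ExpressionRow:
    fold_change: float
    fold_regulation: float
    p_value: float  # NaN when not computable
    n_replicates: int
    mean_ddct: float


def _paired_p(treated: np.ndarray, control: np.ndarray) -> float:
    diffs = treated - control
    if len(diffs) < 2:
        return float("nan")
    if np.allclose(diffs.std(ddof=1), 0.0):
        return 1.0 if np.allclose(diffs.mean(), 0.0) else 0.0
    return float(stats.ttest_1samp(diffs, 0.0).pvalue)


def ddct_expression(
    treated: Sequence[float], control: Sequence[float]
) -> ExpressionRow:
    """Relative expression of one gene from treated and control dCt replicates."""
    treated = np.asarray(list(treated), dtype=float)
    control = np.asarray(list(control), dtype=float)
    if len(treated) == 0 or len(control) == 0:
        raise MissingDataError("need at least one treated and one control replicate")
    ddct = float(treated.mean() - control.mean())
    fc = float(2.0 ** -ddct)
    if len(treated) == len(control):
        p = _paired_p(treated, control)
    elif len(treated) >= 2 and len(control) >= 2:
        p = float(stats.ttest_ind(treated, control, equal_var=False).pvalue)
    else:
        p = float("nan")
    return ExpressionRow(
        fold_change=fc,
        fold_regulation=fold_regulation(fc),
        p_value=p,
        n_replicates=min(len(treated), len(control)),
        mean_ddct=ddct,
    )


def qc_range_check(fc_array: float, fc_rtqpcr: float, tolerance_fold: float = 3.0) -> bool:
    """Cross-platform agreement: fold changes within ``tolerance_fold`` of
    each other pass."""
    if fc_array <= 0 or fc_rtqpcr <= 0 or tolerance_fold <= 0:
        raise DomainError("fold changes and tolerance must be positive")
    hi, lo = max(fc_array, fc_rtqpcr), min(fc_array, fc_rtqpcr)
    return hi / lo <= tolerance_fold


# ---------------------------------------------------------------------------
# table-level quantification

EXPRESSION_COLUMNS = [
    "cell_line", "substance", "gene", "fold_change", "fold_regulation",
    "p_value", "n_replicates", "mean_ddct", "censored", "deg_eligible",
]


def quantify(
    ct_table: pd.DataFrame,
    housekeeping: Sequence[str],
    ct_cutoff: float = 35.0,
    control_group: str = "untreated_control",
) -> pd.DataFrame:
    """Full ddCt quantification of a long-format Ct table.

    One output row per (cell_line, substance, gene).  Genes censored at the
    Ct cutoff in every treated and every control replicate are reported with
    fold_change 1 and marked ineligible for differential-expression calling
    (the ratio of two censored values carries no information).
    """
    housekeeping = list(housekeeping)
    rows = []
    df = ct_table.copy()
    undet = df["ct"].isna() if "undetected" not in df else df["undetected"]
    censored_mask = undet | (df["ct"] > ct_cutoff)
    df["ct"] = np.where(censored_mask, ct_cutoff, df["ct"])
    df["censored"] = censored_mask

    for (cell_line, substance), grp in df.groupby(["cell_line", "substance"], sort=True):
        for group_label in ("treated", control_group):
            if not (grp["group"] == group_label).any():
                raise MissingDataError(
                    f"{cell_line}/{substance}: no {group_label} samples in Ct table"
                )
        mats = {}
        cens = {}
        for label in ("treated", control_group):
            sub = grp[grp["group"] == label]
            mat = sub.pivot(index="gene", columns="sample_id", values="ct")
            cmat = sub.pivot(index="gene", columns="sample_id", values="censored")
            missing_hk = [g for g in housekeeping if g not in mat.index]
            if missing_hk:
                raise NormalizationError(
                    f"{cell_line}/{substance}/{label}: housekeeping gene(s) {missing_hk} missing"
                )
            hk_undet = cmat.loc[housekeeping]
            if hk_undet.to_numpy().any():
                bad = sorted(hk_undet.index[hk_undet.any(axis=1)])
                raise NormalizationError(
                    f"{cell_line}/{substance}/{label}: housekeeping gene(s) {bad} undetected"
                )
            # sample-wise dCt, replicate columns in stable (sorted) order
            mat = mat.reindex(sorted(mat.columns), axis=1)
            dct = mat - mat.loc[housekeeping].mean(axis=0)
            mats[label] = dct.drop(index=[g for g in housekeeping if g in dct.index])
            cens[label] = cmat.reindex(mat.columns, axis=1).drop(
                index=[g for g in housekeeping if g in cmat.index]
            )

        genes = sorted(set(mats["treated"].index) & set(mats[control_group].index))
        t_mat = mats["treated"].loc[genes].to_numpy(float)
        c_mat = mats[control_group].loc[genes].to_numpy(float)
        t_cens = cens["treated"].loc[genes].to_numpy(bool)
        c_cens = cens[control_group].loc[genes].to_numpy(bool)
        all_censored = t_cens.all(axis=1) & c_cens.all(axis=1)

        ddct = t_mat.mean(axis=1) - c_mat.mean(axis=1)
        if t_mat.shape[1] == c_mat.shape[1] and t_mat.shape[1] >= 2:
            diffs = t_mat - c_mat
            sd = diffs.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = stats.ttest_1samp(diffs, 0.0, axis=1).pvalue
            degenerate = np.isclose(sd, 0.0)
            p = np.where(degenerate, np.where(np.isclose(diffs.mean(axis=1), 0.0), 1.0, 0.0), p)
        elif t_mat.shape[1] >= 2 and c_mat.shape[1] >= 2:
            p = stats.ttest_ind(t_mat, c_mat, axis=1, equal_var=False).pvalue
        else:
            p = np.full(len(genes), np.nan)

        ddct = np.where(all_censored, 0.0, ddct)
        fc = 2.0 ** -ddct
        fr = np.where(fc >= 1, fc, -1.0 / fc)
        for i, gene in enumerate(genes):
            rows.append(
                {
                    "cell_line": cell_line,
                    "substance": substance,
                    "gene": gene,
                    "fold_change": fc[i],
                    "fold_regulation": fr[i],
                    "p_value": np.nan if all_censored[i] else p[i],
                    "n_replicates": min(t_mat.shape[1], c_mat.shape[1]),
                    "mean_ddct": ddct[i],
                    "censored": bool(t_cens[i].any() or c_cens[i].any()),
                    "deg_eligible": not all_censored[i],
                }
            )
    return pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)
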