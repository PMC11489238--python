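"""Viability normalization and selection of the highest non-cytotoxic
concentration.

Two readouts are supported: the WST-1 tetrazolium assay (absorbance at a
signal wavelength related to a 620 nm reference, blank-corrected) and the
neutral-red uptake assay (fluorescence, blank-corrected).  Both are expressed
as percent of the solvent control.  Downstream exposure uses the largest
tested concentration at which every provided assay stays above the viability
threshold (strictly greater than 80% by default), plus a second concentration
at 0.33x that value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import pandas as pd

from .errors import DegenerateControlError, SchemaError, SelectionError


@dataclass(frozen=True)
class CurvePoint:
    concentration: float
    viability: float  # percent of solvent control, mean over technical replicates
    n_replicates: int = 1


@dataclass
class ViabilityCurve:
    substance: str
    cell_line: str
    assay: str  # "WST1" or "NR"
    points: List[CurvePoint]

    def __post_init__(self):
        concs = [p.concentration for p in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if any(p.viability < 0 for p in self.points):
            raise ValueError("viability must be non-negative")

    def viability_at(self, concentration: float) -> float:
        for p in self.points:
            if p.concentration == concentration:
                return p.viability
        raise KeyError(concentration)

    @property
    def concentrations(self) -> List[float]:
        return [p.concentration for p in self.points]


def normalize_absorbance(
    a_signal: float,
    a_reference: float,
    blank_signal: float,
    blank_reference: float,
    control_net: float,
) -> float:
    """Percent viability from a dual-wavelength absorbance reading.

    The signal reading is related to the reference-wavelength reading, the
    blank net value is subtracted, and the result is expressed relative to
    the solvent-control net value.
    """
    if control_net <= 0:
        raise DegenerateControlError(f"control net absorbance must be positive, got {control_net}")
    net = (a_signal - a_reference) - (blank_signal - blank_reference)
    return 100.0 * net / control_net


def normalize_fluorescence(signal: float, blank: float, control_net: float) -> float:
    """Percent viability from a fluorescence reading with one blank term."""
    if control_net <= 0:
        raise DegenerateControlError(f"control net fluorescence must be positive, got {control_net}")
    return 100.0 * (signal - blank) / control_net


@dataclass(frozen=True)
class SelectedConcentration:
    concentration: float
    top_of_range: bool  # even the maximum tested concentration passed


def select_highest_noncytotoxic(
    curves: Sequence[ViabilityCurve], threshold: float = 80.0
) -> SelectedConcentration:
    """Largest tested concentration passing the viability rule in every assay.

    When several assays are provided the rule is a conjunction: a
    concentration qualifies only if each assay's mean viability is strictly
    above the threshold there.  Only concentrations tested in all assays are
    eligible.
    """
    if not curves:
        raise SelectionError("no viability curves provided")
    eligible = set(curves[0].concentrations)
    for c in curves[1:]:
        eligible &= set(c.concentrations)
    if not eligible:
        raise SelectionError("assays share no tested concentration")
    passing = [
        conc
        for conc in sorted(eligible)
        if all(curve.viability_at(conc) > threshold for curve in curves)
    ]
    if not passing:
        raise SelectionError(
            f"no concentration passes viability > {threshold}%; test a lower range"
        )
    top = max(max(c.concentrations) for c in curves)
    best = max(passing)
    return SelectedConcentration(concentration=best, top_of_range=best == top)


def second_concentration(c_high: float) -> float:
    """The lower exposure concentration: 0.33 x the highest non-cytotoxic."""
    return 0.33 * c_high


# ---------------------------------------------------------------------------
# plate-reading ingestion

PLATE_COLUMNS = ["substance", "cell_line", "assay", "concentration", "role", "signal"]


def curves_from_plate(df: pd.DataFrame) -> List[ViabilityCurve]:
    """Build viability curves from raw plate readings.

    Expected columns: substance, cell_line, assay (WST1|NR), concentration,
    role (blank|control|treated), signal and — for WST1 — reference.
    Technical replicates are averaged before normalization.
    """
    for col in PLATE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"plate table: missing required column {col!r}")
    curves = []
    for (substance, cell_line, assay), grp in df.groupby(
        ["substance", "cell_line", "assay"], sort=True
    ):
        def net(rows) -> float:
            if assay == "WST1":
                if "reference" not in df.columns:
                    raise SchemaError("plate table: WST1 readings need a 'reference' column")
                return float((rows["signal"] - rows["reference"]).mean())
            return float(rows["signal"].mean())

        blank = net(grp[grp["role"] == "blank"])
        control_net = net(grp[grp["role"] == "control"]) - blank
        if control_net <= 0:
            raise DegenerateControlError(
                f"{substance}/{cell_line}/{assay}: control net signal must be positive"
            )
        points = []
        treated = grp[grp["role"] == "treated"]
        for conc, rows in treated.groupby("concentration", sort=True):
            viability = 100.0 * (net(rows) - blank) / control_net
            points.append(CurvePoint(float(conc), max(viability, 0.0), len(rows)))
        curves.append(ViabilityCurve(substance, cell_line, assay, points))
    return curves
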