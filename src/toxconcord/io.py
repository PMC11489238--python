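"""Delimited-file input/output and packaged ontologies.

All files are UTF-8, comma-separated, header row mandatory.  Numeric fields
written by German-locale spreadsheet tooling use a decimal comma; values are
normalized on read.  Ct fields that are non-numeric after normalization
("Undetermined", "NA", blank) are flagged undetected rather than dropped.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Sequence

import pandas as pd

from .concordance import ORGANS, EffectMapping, InVivoProfile, MappingRule
from .errors import InputError, SchemaError, VocabularyError

logger = logging.getLogger(__name__)

CT_COLUMNS = [
    "sample_id", "cell_line", "substance", "concentration", "time", "group", "gene", "ct",
]
PROTEIN_COLUMNS = [
    "marker", "cell_line", "substance", "concentration", "time", "replicate", "value",
]
ANNOTATION_COLUMNS = ["category", "annotation", "p_overlap", "n_deg", "deg_names"]

#: group labels recognised in Ct tables
CT_GROUPS = ("treated", "solvent_control", "untreated_control")


def packaged_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(resources.files("toxconcord.data") / name)


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8", **kw)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty input file: {path}") from exc
    if df.empty and df.columns.empty:
        raise InputError(f"empty input file: {path}")
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def to_numeric_locale(series: pd.Series) -> pd.Series:
    """Parse numbers written with either a decimal point or a decimal comma."""
    s = series.astype(str).str.strip().str.replace(",", ".", regex=False)
    return pd.to_numeric(s, errors="coerce")


# ---------------------------------------------------------------------------
# Ct tables


def load_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct table.

    Returns a DataFrame with the schema columns, numeric ``ct`` (NaN where
    undetected), a boolean ``undetected`` flag, and ``is_housekeeping``
    (defaults to False when the file does not carry it).
    """
    df = _read_csv(path)
    _require_columns(df, CT_COLUMNS, path)
    if df.empty:
        raise InputError(f"{path}: no records")
    out = df.copy()
    out["concentration"] = to_numeric_locale(out["concentration"])
    out["time"] = to_numeric_locale(out["time"])
    ct = to_numeric_locale(out["ct"])
    out["undetected"] = ct.isna()
    out["ct"] = ct
    n_undet = int(out["undetected"].sum())
    if n_undet:
        logger.info("load_ct_table: %d records flagged undetected (reason=non_numeric_ct)", n_undet)
    if "is_housekeeping" in out.columns:
        out["is_housekeeping"] = (
            out["is_housekeeping"].astype(str).str.strip().str.lower().isin(("1", "true", "yes"))
        )
    else:
        out["is_housekeeping"] = False
    bad = ~out["group"].isin(CT_GROUPS)
    if bad.any():
        raise SchemaError(
            f"{path}: unknown group label(s) {sorted(out.loc[bad, 'group'].unique())}; "
            f"expected one of {CT_GROUPS}"
        )
    return out


def write_ct_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["ct"] = out["ct"].map(lambda v: "Undetermined" if pd.isna(v) else f"{v:.6g}")
    out.drop(columns=[c for c in ("undetected",) if c in out], inplace=True)
    out.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# ontologies


def load_vocabulary(path=None) -> Dict[str, FrozenSet[str]]:
    """Controlled vocabulary of in vivo effect categories per organ."""
    df = _read_csv(path or packaged_path("effect_vocabulary.csv"))
    _require_columns(df, ["organ", "effect"], path or "effect_vocabulary.csv")
    return {
        organ: frozenset(df.loc[df["organ"] == organ, "effect"])
        for organ in ORGANS
    }


def _check_vocab(effect: str, organ: str, vocab: Dict[str, FrozenSet[str]], context: str) -> None:
    if effect not in vocab.get(organ, frozenset()):
        valid = sorted(vocab.get(organ, frozenset()))
        raise VocabularyError(
            f"{context}: unknown effect category {effect!r} for organ {organ!r}; "
            f"valid terms: {valid}"
        )


def load_ontology(path=None, kind: str = "in_vivo", vocabulary=None):
    """Load one of the packaged ontologies (or a user override).

    ``kind`` is one of ``in_vivo`` (substance effect profiles),
    ``protein_map`` (cellular function -> effects) or ``category_map``
    (pathway-analysis category combinations -> effects).
    """
    vocab = vocabulary or load_vocabulary()
    if kind == "in_vivo":
        df = _read_csv(path or packaged_path("in_vivo_profiles.csv"))
        _require_columns(df, ["substance", "organ", "effect"], path or "in_vivo_profiles.csv")
        effects: Dict[str, Dict[str, set]] = {}
        for row in df.itertuples(index=False):
            if not row.effect:
                effects.setdefault(row.substance, {}).setdefault(row.organ, set())
                continue
            _check_vocab(row.effect, row.organ, vocab, f"in_vivo profile of {row.substance}")
            effects.setdefault(row.substance, {}).setdefault(row.organ, set()).add(row.effect)
        return InVivoProfile(
            effects={
                s: {o: frozenset(v) for o, v in orgs.items()} for s, orgs in effects.items()
            }
        )
    if kind == "protein_map":
        df = _read_csv(path or packaged_path("protein_effect_map.csv"))
        _require_columns(df, ["cellular_function", "organ", "effect"], path or "protein_effect_map.csv")
        grouped: Dict[tuple, set] = {}
        for row in df.itertuples(index=False):
            key = ((row.cellular_function,), row.organ)
            grouped.setdefault(key, set())
            if row.effect:
                _check_vocab(row.effect, row.organ, vocab, f"protein map {row.cellular_function}")
                grouped[key].add(row.effect)
        rules = [
            MappingRule(members=m, organ=o, targets=frozenset(t))
            for (m, o), t in grouped.items()
        ]
        return EffectMapping(kind="protein", rules=rules)
    if kind == "category_map":
        df = _read_csv(path or packaged_path("ipa_effect_map.csv"))
        _require_columns(df, ["categories", "organ", "effect"], path or "ipa_effect_map.csv")
        grouped = {}
        for row in df.itertuples(index=False):
            members = tuple(part.strip() for part in row.categories.split("|"))
            key = (members, row.organ)
            grouped.setdefault(key, set())
            if row.effect:
                _check_vocab(row.effect, row.organ, vocab, f"category map {row.categories}")
                grouped[key].add(row.effect)
        rules = [
            MappingRule(members=m, organ=o, targets=frozenset(t))
            for (m, o), t in grouped.items()
        ]
        return EffectMapping(kind="category", rules=rules)
    raise ValueError(f"unknown ontology kind {kind!r}; expected in_vivo, protein_map or category_map")


def load_category_whitelist(path=None) -> FrozenSet[str]:
    """Liver/kidney disease-or-function categories accepted for scoring."""
    df = _read_csv(path or packaged_path("ipa_category_whitelist.csv"))
    _require_columns(df, ["category"], path or "ipa_category_whitelist.csv")
    return frozenset(df["category"])


def load_marker_functions(path=None) -> Dict[str, str]:
    """Protein marker -> cellular function (the 8-analyte panel)."""
    df = _read_csv(path or packaged_path("protein_markers.csv"))
    _require_columns(df, ["marker", "cellular_function"], path or "protein_markers.csv")
    return dict(zip(df["marker"], df["cellular_function"]))


# ---------------------------------------------------------------------------
# panels and catalogs


def load_panel_manifest(path) -> Dict[str, list]:
    """Array manifest: target genes and housekeeping genes."""
    df = _read_csv(path)
    _require_columns(df, ["gene", "role"], path)
    return {
        "targets": list(df.loc[df["role"] == "target", "gene"]),
        "housekeeping": list(df.loc[df["role"] == "housekeeping", "gene"]),
    }


def packaged_panel(cell_line: str) -> Dict[str, list]:
    name = {"HepaRG": "liver_panel_synthetic.csv", "RPTEC": "kidney_panel_synthetic.csv"}[cell_line]
    return load_panel_manifest(packaged_path(name))


def load_catalog_file(path, collection: Optional[str] = None) -> Dict[str, FrozenSet[str]]:
    """Two-or-four-column pathway/gene file -> pathway -> gene set."""
    df = _read_csv(path)
    _require_columns(df, ["pathway", "gene"], path)
    if collection is not None and "collection" in df.columns:
        df = df[df["collection"] == collection]
    return {
        pw: frozenset(grp["gene"]) for pw, grp in df.groupby("pathway", sort=True)
    }


def packaged_catalog(cell_line: str, collection: str = "ipa_category") -> Dict[str, FrozenSet[str]]:
    name = {
        "HepaRG": "liver_catalog_synthetic.csv",
        "RPTEC": "kidney_catalog_synthetic.csv",
    }[cell_line]
    return load_catalog_file(packaged_path(name), collection=collection)


# ---------------------------------------------------------------------------
# protein panels and annotation exports


def load_protein_panel(path) -> pd.DataFrame:
    """Long-format protein panel: one row per replicate measurement."""
    df = _read_csv(path)
    _require_columns(df, PROTEIN_COLUMNS, path)
    if df.empty:
        raise InputError(f"{path}: no records")
    out = df.copy()
    for col in ("concentration", "time", "value"):
        out[col] = to_numeric_locale(out[col])
    if (out["value"] <= 0).any() or out["value"].isna().any():
        raise SchemaError(f"{path}: protein values must be positive percent-of-control numbers")
    return out


def load_annotation_export(path, substance: str, input_scope: str):
    """Read a pathway-analysis export (category, annotation, p-value, genes)."""
    from .transcript import AnnotationRecord

    df = _read_csv(path)
    _require_columns(df, ["category", "annotation", "p_overlap"], path)
    records = []
    for row in df.itertuples(index=False):
        p = float(str(row.p_overlap).replace(",", "."))
        n_deg = int(getattr(row, "n_deg", 0) or 0)
        names = tuple(x for x in str(getattr(row, "deg_names", "")).split(";") if x)
        records.append(
            AnnotationRecord(
                substance=substance,
                input_scope=input_scope,
                category=row.category,
                annotation=row.annotation,
                p_overlap=p,
                n_deg=n_deg,
                deg_names=names,
            )
        )
    return records


# ---------------------------------------------------------------------------
# writers


def write_table(df: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a delimited table deterministically (fixed float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", float_format=float_format)


def in_vivo_to_frame(profile: InVivoProfile) -> pd.DataFrame:
    rows = [
        {"substance": s, "organ": o, "effect": e}
        for s, orgs in sorted(profile.effects.items())
        for o, effs in sorted(orgs.items())
        for e in sorted(effs)
    ]
    return pd.DataFrame(rows, columns=["substance", "organ", "effect"])
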