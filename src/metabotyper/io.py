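"""TSV/JSON readers and writers for the documented table interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

TIMECOURSE_COLUMNS = [
    "individual",
    "timepoint_min",
    "replicate",
    "area_sn38",
    "area_sn38g",
    "area_istd",
]
CALIBRATION_COLUMNS = ["metabolite", "concentration_uM", "area_ratio"]
REACTION_COLUMNS = ["enzyme_id", "substrates", "products"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_timecourse(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    return df


def read_calibration(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CALIBRATION_COLUMNS, path)
    return df


def read_reactions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, REACTION_COLUMNS, path)
    return df


def read_feature_table(path) -> pd.DataFrame:
    """Feature matrix TSV: first column feature_id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "feature_id":
        raise SchemaError(f"{path}: first column must be 'feature_id'")
    df = df.set_index("feature_id")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise SchemaError(f"{path}: non-numeric sample column(s) {non_numeric}")
    return df


def read_labels(path) -> pd.Series:
    """Assignment TSV with at least (individual, metabotype) columns."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["individual", "metabotype"], path)
    return df.set_index("individual")["metabotype"]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
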