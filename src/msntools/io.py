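"""Readers and writers for the pipeline's tabular formats.

All tables are plain TSV; summaries are JSON with sorted keys and no
timestamps, so fixed-seed reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .msn import FEATURE_NAMES, MorphometryTable, validate_subjects
from .parcellation import Parcellation
from .synthetic import ExpressionMatrix


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_id": parcellation.region_id,
            "name": parcellation.name,
            "hemisphere": parcellation.hemisphere,
            "cx": parcellation.centroids[:, 0],
            "cy": parcellation.centroids[:, 1],
            "cz": parcellation.centroids[:, 2],
            "yeo": parcellation.yeo,
            "von_economo": parcellation.von_economo,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_parcellation(path: str | Path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    centroids = df[["cx", "cy", "cz"]].to_numpy(float)
    # renormalise against decimal round-trip error
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    return Parcellation(
        region_id=df["region_id"].to_numpy(int),
        name=list(df["name"]),
        hemisphere=df["hemisphere"].to_numpy(str),
        centroids=centroids,
        yeo=df["yeo"].to_numpy(str),
        von_economo=df["von_economo"].to_numpy(str),
    )


def write_morphometry(table: MorphometryTable, values_path: str | Path, subjects_path: str | Path) -> None:
    """Long-format morphometry TSV (subject, region_id, feature, value) plus
    a subjects TSV (subject, group, age, sex, tiv, attendance)."""
    S, R, F = table.values.shape
    sid = np.repeat(table.subjects["subject_id"].to_numpy(), R * F)
    region = np.tile(np.repeat(np.arange(R), F), S)
    feature = np.tile(np.asarray(table.feature_names), S * R)
    long = pd.DataFrame(
        {"subject": sid, "region_id": region, "feature": feature, "value": table.values.ravel()}
    )
    long.to_csv(values_path, sep="\t", index=False, float_format="%.17g")
    table.subjects.to_csv(subjects_path, sep="\t", index=False, float_format="%.17g")


def read_morphometry(values_path: str | Path, subjects_path: str | Path) -> MorphometryTable:
    subjects = validate_subjects(pd.read_csv(subjects_path, sep="\t"))
    long = pd.read_csv(values_path, sep="\t")
    if long["value"].isna().any():
        raise ValueError("missing morphometry values; impute or drop before ingestion")
    wide = long.pivot_table(
        index="subject", columns=["region_id", "feature"], values="value", sort=False
    )
    R = long["region_id"].nunique()
    order = subjects["subject_id"].to_numpy()
    cols = pd.MultiIndex.from_product([np.arange(R), FEATURE_NAMES])
    values = wide.loc[order, cols].to_numpy(float).reshape(len(order), R, len(FEATURE_NAMES))
    return MorphometryTable(values=values, subjects=subjects)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.gene_symbols)
    df.insert(0, "region_id", expr.region_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    region_ids = df.pop("region_id").to_numpy(int)
    return ExpressionMatrix(
        values=df.to_numpy(float), gene_symbols=list(df.columns), region_ids=region_ids
    )


def write_strengths(strengths: pd.DataFrame, path: str | Path) -> None:
    strengths.to_csv(path, sep="\t", float_format="%.17g")


def read_strengths(path: str | Path, kind: str = "ms") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(int)
    df.attrs["kind"] = kind
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
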