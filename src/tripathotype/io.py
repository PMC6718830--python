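"""Readers and writers for the pipeline's plain-text formats.

Counts and expression matrices are TSV with genes in rows and a header
row of sample/tissue ids; gene sets are GMT (name, description, then
tab-separated gene ids); sample tables are CSV keyed on ``sample_id``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import GeneModule

FLOAT_FORMAT = "%.10g"  # stable text round-trip for determinism checks


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate gene or sample ids")
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_counts_tsv(path) -> pd.DataFrame:
    df = read_matrix_tsv(path)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError(f"{path}: counts are not integers")
        df = df.round().astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def read_sample_table_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")


def write_sample_table_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(0, "sample_id", out.index.astype(str))
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_gmt(path) -> list[GeneModule]:
    modules = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description and >=1 gene")
        name, _desc, *genes = parts
        modules.append(GeneModule(label=name, genes=[g for g in genes if g]))
    return modules


def write_gmt(modules: Iterable[GeneModule], path, description: str = "tripathotype") -> None:
    lines = []
    for m in modules:
        lines.append("\t".join([m.label, description, *m.genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return {"index": list(o.index), "columns": list(o.columns), "data": o.to_numpy().tolist()}
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    return json.loads(Path(path).read_text())
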