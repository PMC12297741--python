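"""Tabular I/O: survey loading with a codebook, and network table export.

All numeric CSV output is written at full double precision (``repr``
round-trip) so that re-reading a written artifact reproduces the computed
values bit-for-bit.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import as_weight_matrix
from .params import LikertSurvey

__all__ = ["load_survey", "write_csv", "write_network_tables", "sha256_file"]


def load_survey(
    items_path, codebook_path, id_column: str = "participant_id"
) -> tuple[LikertSurvey, pd.DataFrame]:
    """Read an item CSV plus its codebook; returns (survey, covariate table).

    The codebook must have columns ``item_id``, ``scale`` and
    ``reverse_keyed`` (yes/no) and cover every item; columns of the items
    file not listed in the codebook (apart from the participant id) are
    returned as covariates.
    """
    items_path, codebook_path = Path(items_path), Path(codebook_path)
    for path in (items_path, codebook_path):
        if not path.exists() or path.stat().st_size == 0:
            raise ValueError(f"missing or empty file: {path}")
    codebook = pd.read_csv(codebook_path)
    required = {"item_id", "scale", "reverse_keyed"}
    if not required.issubset(codebook.columns):
        raise ValueError(f"codebook must have columns {sorted(required)}")
    table = pd.read_csv(items_path)
    if len(table) == 0:
        raise ValueError(f"no data rows in {items_path}")
    if id_column in table.columns:
        if table[id_column].duplicated().any():
            dup = table[id_column][table[id_column].duplicated()].iloc[0]
            raise ValueError(f"duplicated participant id: {dup!r}")
        table = table.set_index(id_column)
    item_ids = [str(i) for i in codebook["item_id"]]
    missing = [i for i in item_ids if i not in table.columns]
    if missing:
        raise ValueError(f"codebook items absent from the data: {missing}")
    items = table[item_ids]
    for col in item_ids:
        vals = items[col].dropna()
        if not np.all(np.asarray(vals, dtype=float) % 1 == 0):
            raise ValueError(f"non-integer Likert response in item {col!r}")
    reverse = {
        str(r.item_id)
        for r in codebook.itertuples()
        if str(r.reverse_keyed).strip().lower() in ("yes", "true", "1")
    }
    scale_map = {str(r.item_id): str(r.scale) for r in codebook.itertuples()}
    survey = LikertSurvey(items.astype("Int64"), reverse, scale_map)
    covariates = table.drop(columns=item_ids)
    return survey, covariates


def write_csv(df: pd.DataFrame, path, index: bool = True) -> Path:
    """Write a CSV with repr-round-trip float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format=lambda v: repr(float(v)))
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def network_to_edge_frame(network) -> pd.DataFrame:
    labels, W = as_weight_matrix(network)
    rows = []
    p = len(labels)
    for i in range(p):
        for j in range(i + 1, p):
            rows.append((labels[i], labels[j], float(W[i, j])))
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def write_network_tables(
    networks: dict, node_tables: dict | None = None, extra_tables: dict | None = None,
    outdir=".",
) -> pd.DataFrame:
    """Write long-format edge CSVs, node-metric CSVs and any extra tables.

    Returns a manifest DataFrame (file name, sha256 content hash), itself
    written alongside the artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, net in (networks or {}).items():
        written.append(write_csv(network_to_edge_frame(net), outdir / f"{name}_edges.csv",
                                 index=False))
    for name, table in (node_tables or {}).items():
        written.append(write_csv(table, outdir / f"{name}.csv"))
    for name, table in (extra_tables or {}).items():
        written.append(write_csv(table, outdir / f"{name}.csv",
                                 index=not isinstance(table.index, pd.RangeIndex)))
    manifest = pd.DataFrame(
        sorted((p.name, sha256_file(p)) for p in written), columns=["file", "sha256"]
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
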