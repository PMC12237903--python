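"""Readers and writers for the pipeline's plain-text formats.

OTU tables use the classic tab-separated layout (first column ``#OTU ID``,
one column per sample, integer counts).  Taxonomy is a two-column TSV.
Edge catalogs and per-node tables are long-form TSVs; networks are GraphML;
reports and configs are JSON with stable float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import EDGE_COLUMNS, OtuTable, TaxonomyMap

OTU_HEADER = "#OTU ID"


def write_otu_table(table: OtuTable, path) -> None:
    df = table.df.copy()
    df.index.name = OTU_HEADER
    df.to_csv(path, sep="\t")


def read_otu_table(path) -> OtuTable:
    """Parse a classic TSV OTU table, rejecting malformed cells by name."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.index.name != OTU_HEADER:
        raise ValueError(f"expected first column {OTU_HEADER!r}, got {df.index.name!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate OTU ids: {dup}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.round(vals))
        if bad.any():
            otu = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"non-integer or negative count at OTU {otu!r}, sample {col!r}")
        df[col] = vals.astype(np.int64)
    return OtuTable(df)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#OTU ID\tlineage\n")
        for otu, lineage in tax.lineages.items():
            fh.write(f"{otu}\t{lineage}\n")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TaxonomyMap(df.iloc[:, 0].to_dict())


def read_metadata(path) -> pd.Series:
    """Sample metadata TSV with columns ``sample_id`` and ``site``."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "site"} <= set(df.columns):
        raise ValueError("metadata must have columns sample_id and site")
    return df.set_index("sample_id")["site"]


def write_edge_catalog(catalog: pd.DataFrame, path) -> None:
    catalog[EDGE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_edge_catalog(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: np.ndarray, ids, path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
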