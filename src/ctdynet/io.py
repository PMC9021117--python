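"""File formats: time-series CSV (wide/long), labeled matrix CSV, model JSON,
and network export (edge list / GraphML).

Times are expected in a consistent unit (hours by convention); the package
never guesses units. All CSV outputs are tidy and self-describing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import networkx as nx

from .model_core import CTModel, DTModel, IrregularTimeSeries, load_model

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "export_network",
    "network_edgelist",
    "load_model",
]

log = logging.getLogger("ctdynet")

#: float format used for every CSV written by the package; fixed so that
#: identical inputs yield byte-identical outputs
CSV_FLOAT_FORMAT = "%.12g"


def read_timeseries_csv(path, time_col: str = "time", var_cols=None,
                        layout: str = "wide") -> IrregularTimeSeries:
    """Read a timestamped multivariate series from CSV.

    Wide layout: one row per occasion, one column per variable. Long layout:
    (time, variable, value) triplets, pivoted to wide. Rows are sorted by
    time; duplicated timestamps are an error; non-numeric cells become
    missing values with a logged count.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    if time_col not in df.columns:
        raise ValueError(f"missing time column {time_col!r} in {path}")

    if layout == "long":
        needed = {time_col, "variable", "value"}
        if not needed.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(needed)}")
        df = df.pivot_table(index=time_col, columns="variable", values="value",
                            aggfunc="first").reset_index()
        df.columns.name = None

    if var_cols is None:
        var_cols = [c for c in df.columns if c != time_col]
    missing_cols = [c for c in var_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing variable columns {missing_cols} in {path}")

    df = df.sort_values(time_col, kind="mergesort").reset_index(drop=True)
    times = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
    dup = pd.Series(times).duplicated()
    if dup.any():
        t_bad = times[dup.to_numpy()][0]
        raise ValueError(f"duplicated timestamp t={t_bad!r} in {path}")

    vals = df[list(var_cols)].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    n_coerced = int(np.sum(np.isnan(vals)) - df[list(var_cols)].isna().to_numpy().sum())
    if n_coerced > 0:
        log.warning("%d non-numeric cells coerced to missing in %s", n_coerced, path)
    return IrregularTimeSeries(times=times, values=vals, labels=list(var_cols))


def write_timeseries_csv(data: IrregularTimeSeries, path, time_col: str = "time") -> None:
    df = pd.DataFrame(data.values, columns=list(data.labels))
    df.insert(0, time_col, data.times)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix (header row + index column of labels)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix CSV must have identical row and column labels")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_matrix_csv(matrix: np.ndarray, labels, path) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, float_format=CSV_FLOAT_FORMAT
    )


def network_edgelist(model: CTModel | DTModel) -> pd.DataFrame:
    """Tidy edge list of a network model; zero-weight edges are omitted.

    The weight of edge (from, to) is ``M[to, from]`` with M the drift (CT) or
    lagged (DT) matrix; type is "auto" for self-edges, "cross" otherwise.
    """
    mat = model.drift if isinstance(model, CTModel) else model.lagged
    rows = []
    for i, src in enumerate(model.labels):  # cause
        for j, dst in enumerate(model.labels):  # effect
            w = mat[j, i]
            if w != 0.0:
                rows.append((src, dst, w, "auto" if i == j else "cross"))
    return pd.DataFrame(rows, columns=["from", "to", "weight", "type"])


def export_network(model: CTModel | DTModel, path, format: str = "edgelist_csv") -> None:
    """Write a model's network to disk as an edge-list CSV or GraphML file.

    GraphML output carries node labels, edge weights, and a graph-level
    ``model_kind`` attribute ("ct" or "dt") so renderers can distinguish
    local-dependence graphs (conventionally drawn with hexagonal nodes) from
    DT-VAR networks.
    """
    kind = "ct" if isinstance(model, CTModel) else "dt"
    if format == "edgelist_csv":
        network_edgelist(model).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    elif format == "graphml":
        g = nx.DiGraph(model_kind=kind)
        for lab in model.labels:
            g.add_node(lab, label=lab)
        for _, row in network_edgelist(model).iterrows():
            g.add_edge(row["from"], row["to"], weight=float(row["weight"]),
                       type=row["type"])
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network export format {format!r}")
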