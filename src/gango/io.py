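"""Plain-text I/O: TSV time series, partitions, graphs, and tables.

Time series are samples × parcels TSV with a header row of parcel ids.
Multi-run inputs are z-scored per column within each run and then
concatenated row-wise, so run-level scale differences cannot leak into
the covariance. Graphs travel as edge-list TSV (source, target [, type])
or as square 0/1 adjacency-matrix TSV; partitions as two-column TSV
(parcel id, module label). Parcel ids are opaque strings externally and
0-based indices internally.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .graphs import DirectedConnectome, MixedGraph
from .partition import NetworkPartition

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_partition",
    "write_partition",
    "write_graph",
    "read_graph",
    "write_matrix",
    "write_table",
]


def _read_one_run(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set = set()
    dups = [h for h in header if h in seen or seen.add(h)]
    if dups:
        raise InputError(f"{path}: duplicate parcel id(s) {sorted(set(dups))}")
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except Exception as exc:
        raise InputError(f"{path}: cannot parse TSV ({exc})") from exc
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for k, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                line = int(bad.isna().idxmax()) + 2  # +1 header, +1 one-based
                raise InputError(f"{path}: non-numeric cell in column {col!r}, line {line}")
        raise InputError(f"{path}: non-numeric data")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{path}: non-finite values in data")
    return df


def read_timeseries(paths, zscore_runs: bool | None = None) -> pd.DataFrame:
    """Read one or more runs; multiple runs are z-scored and concatenated.

    ``zscore_runs`` defaults to True when several paths are given (each
    run standardized per column before concatenation) and False for a
    single run.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    runs = [_read_one_run(p) for p in paths]
    cols = list(runs[0].columns)
    for p, r in zip(paths[1:], runs[1:]):
        if list(r.columns) != cols:
            raise InputError(f"{p}: parcel ids differ from first run")
    if zscore_runs is None:
        zscore_runs = len(runs) > 1
    if zscore_runs:
        out = []
        for r in runs:
            a = r.to_numpy(dtype=float)
            sd = a.std(axis=0)
            if np.any(sd == 0):
                bad = [cols[k] for k in np.where(sd == 0)[0]]
                raise InputError(f"constant parcel(s) {bad} cannot be z-scored")
            out.append((a - a.mean(axis=0)) / sd)
        data = np.vstack(out)
    else:
        data = np.vstack([r.to_numpy(dtype=float) for r in runs])
    return pd.DataFrame(data, columns=cols)


def write_timeseries(ts: pd.DataFrame, path) -> None:
    ts.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_partition(path, parcel_ids=None) -> NetworkPartition:
    """Two-column TSV (parcel id, module label) → partition in data order.

    When ``parcel_ids`` is given, the partition is aligned to that
    order and must cover every id.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (parcel id, module label)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(mapping) != len(df):
        raise InputError(f"{path}: duplicate parcel ids in partition")
    if parcel_ids is None:
        return NetworkPartition(tuple(df.iloc[:, 1]))
    missing = [str(p) for p in parcel_ids if str(p) not in mapping]
    if missing:
        raise InputError(f"partition missing parcel(s): {missing}")
    return NetworkPartition(tuple(mapping[str(p)] for p in parcel_ids))


def write_partition(partition: NetworkPartition, path, parcel_ids=None) -> None:
    ids = parcel_ids if parcel_ids is not None else [f"V{i}" for i in range(partition.p)]
    pd.DataFrame({"parcel": ids, "module": list(partition.labels)}).to_csv(
        path, sep="\t", index=False
    )


def write_graph(g, path, parcel_ids=None) -> None:
    """Edge-list TSV; mixed graphs carry a 'type' column."""
    ids = parcel_ids if parcel_ids is not None else [f"V{i}" for i in range(g.p)]
    rows = []
    if isinstance(g, MixedGraph):
        for i, j in sorted(g.directed):
            rows.append({"source": ids[i], "target": ids[j], "type": "directed"})
        for i, j in sorted(g.undirected):
            rows.append({"source": ids[i], "target": ids[j], "type": "undirected"})
    else:
        for i, j in sorted(g.edges):
            rows.append({"source": ids[i], "target": ids[j]})
    pd.DataFrame(rows, columns=["source", "target", "type"][: 3 if isinstance(g, MixedGraph) else 2]).to_csv(
        path, sep="\t", index=False
    )


def read_graph(path, parcel_ids) -> DirectedConnectome | MixedGraph:
    """Edge-list TSV → graph over the given parcel order."""
    idx = {str(p): k for k, p in enumerate(parcel_ids)}
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    unknown = [
        v for v in pd.concat([df["source"], df["target"]]) if v not in idx
    ]
    if unknown:
        raise InputError(f"{path}: unknown parcel id(s) {sorted(set(unknown))}")
    p = len(idx)
    if "type" in df.columns:
        directed = set()
        undirected = set()
        for _, row in df.iterrows():
            pair = (idx[row["source"]], idx[row["target"]])
            (directed if row["type"] == "directed" else undirected).add(pair)
        return MixedGraph(p, frozenset(directed), frozenset(undirected))
    edges = {(idx[s], idx[t]) for s, t in zip(df["source"], df["target"])}
    return DirectedConnectome(p, frozenset(edges))


def write_matrix(g: DirectedConnectome, path, parcel_ids=None) -> None:
    """Square 0/1 adjacency matrix TSV, rows = sources."""
    ids = parcel_ids if parcel_ids is not None else [f"V{i}" for i in range(g.p)]
    pd.DataFrame(g.adjacency_matrix(), index=ids, columns=ids).to_csv(path, sep="\t")


def write_table(rows, path) -> None:
    """Tidy table (DataFrame or list of dicts) to TSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
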