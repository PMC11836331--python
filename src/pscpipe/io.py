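"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrix TSV (genes × samples), sample sheet TSV, edge-list TSV
(node_a, node_b, category), trace CSV (time + one column per ROI), and Ct
TSV.  GMT handling lives in :mod:`pscpipe.enrich`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calcium import TraceSet
from .expression import ExpressionStudy
from .qpcr import validate_ct_table

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_sheet",
    "read_study",
    "read_edge_list",
    "write_edge_list",
    "read_traces_csv",
    "write_traces_csv",
    "read_ct_table",
    "read_gene_list",
    "write_gene_list",
]


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return df


def read_study(matrix_path, samples_path) -> ExpressionStudy:
    return ExpressionStudy(
        matrix=read_expression_tsv(matrix_path),
        samples=read_sample_sheet(samples_path),
    )


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"node_a", "node_b", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    return df


def write_edge_list(network, path) -> None:
    rows = [
        {"node_a": u, "node_b": v, "category": c}
        for u, v, cats in network.graph.edges(data="categories")
        for c in sorted(cats)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "category"]).to_csv(
        path, sep="\t", index=False
    )


def read_traces_csv(path, sampling_hz: float | None = None) -> TraceSet:
    df = pd.read_csv(path)
    time = df.iloc[:, 0].to_numpy(dtype=float)
    traces = df.iloc[:, 1:]
    if sampling_hz is None:
        dt = np.diff(time)
        if len(dt) == 0:
            raise ValueError("trace file has a single time point")
        sampling_hz = 1.0 / float(np.median(dt))
    return TraceSet(time=time, traces=traces, sampling_hz=sampling_hz)


def write_traces_csv(traceset: TraceSet, path) -> None:
    out = traceset.traces.copy()
    out.insert(0, "time_s", traceset.time)
    out.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path, sep="\t"))


def read_gene_list(path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")
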