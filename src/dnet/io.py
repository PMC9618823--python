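"""Readers and writers for every artifact the pipeline touches.

Expression matrices travel as delimited text (genes as rows, timepoint
labels as the header; blank, "NA" or "NaN" cells are missing). Networks are
written as sorted edge lists, partitions and hubs as CSV tables, heatmaps
as TSV plus an optional PNG rendering, and the run manifest as JSON. All
writers sort their output so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect:
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a genes x timepoints expression matrix from TSV/CSV.

    Validates rectangular shape, unique timepoint labels and numeric cells;
    parse failures report the 1-based line number.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}:1: empty file")
    header = lines[0].split(sep)
    columns = header[1:]
    if len(set(columns)) != len(columns):
        raise ParseError(f"{path}:1: duplicate timepoint labels")
    index, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if len(cells) != len(columns) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(columns) + 1} fields, got {len(cells)}"
            )
        index.append(cells[0])
        row = []
        for cell in cells[1:]:
            if cell.strip() in MISSING_TOKENS:
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric cell {cell!r}") from exc
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(index, name="gene_id"), columns=columns)


def write_expression(expr: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    expr.to_csv(path, sep=_sep_for(path, dialect), index_label="gene_id", na_rep="NA")


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Edge list TSV: gene_a <tab> gene_b <tab> weight, pairs sorted."""
    rows = sorted(tuple(sorted((u, v))) + (d.get("weight", 1.0),) for u, v, d in graph.edges(data=True))
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    G = nx.Graph()
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        G.add_edge(fields[0], fields[1], weight=float(fields[2]))
    return G


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_scores(scores, path: str | Path) -> None:
    """Delta_TU score table: gene_id, delta_tu, selected flag."""
    df = pd.DataFrame(
        {
            "gene_id": scores.scores.index,
            "delta_tu": scores.scores.to_numpy(),
            "selected": [g in set(scores.selected) for g in scores.scores.index],
        }
    )
    df.to_csv(path, index=False)


def write_communities(partition, path: str | Path) -> None:
    rows = sorted(partition.assignment.items(), key=lambda kv: (int(kv[1][1:]), kv[0]))
    pd.DataFrame(rows, columns=["gene_id", "community"]).to_csv(path, index=False)


def read_communities(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["gene_id"], df["community"]))


def write_hubs(hubs: pd.DataFrame, path: str | Path) -> None:
    hubs.to_csv(path, index=False, float_format="%.10g")


def write_heatmap(heatmap, path: str | Path) -> None:
    heatmap.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def render_heatmap(heatmap, path: str | Path) -> None:
    """PNG rendering with a diverging blue-white-red palette over [-1, 1]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(6, max(2, 0.12 * heatmap.values.shape[0] + 1))
    )
    im = ax.imshow(
        heatmap.values.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1
    )
    ax.set_xticks(range(heatmap.values.shape[1]))
    ax.set_xticklabels(heatmap.values.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(f"{heatmap.community_label} ({heatmap.values.shape[0]} genes)")
    fig.colorbar(im, ax=ax, label="relative response")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_ordering(ordering, path: str | Path) -> None:
    df = pd.DataFrame(
        ordering.entries, columns=["community", "peak_time", "sign", "magnitude"]
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
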