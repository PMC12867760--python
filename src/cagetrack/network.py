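"""Social-interaction network construction and Cytoscape export.

Each analysis window yields one weighted, undirected graph: nodes are
animals and the edge weight between two animals is their CCR for that
window divided by 10 (so weights live in [0, 10]).  The export is a
tab-delimited table with the exact header ``Source<TAB>Target<TAB>Edge
betweenness`` -- the column name Cytoscape expects for the imported edge
attribute.  Note that despite that header the value is the scaled CCR,
not graph-theoretic betweenness; internally the field is called
``weight``.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "build_edge_table",
    "write_edge_tsv",
    "read_edge_tsv",
    "network_summary",
    "EDGE_TSV_HEADER",
]

EDGE_TSV_HEADER = "Source\tTarget\tEdge betweenness"


def build_edge_table(
    ccr_values: pd.DataFrame,
    tag_order: list[str] | None = None,
    include_zero: bool = True,
) -> pd.DataFrame:
    """One window's pair CCRs -> edge table with ``weight = ccr_pct / 10``.

    ``ccr_values`` must hold one row per unordered pair (columns
    ``tag_i, tag_j, ccr_pct``); pairs with missing CCR are skipped.
    Edges are ordered by ``tag_order`` (source first, then target) when
    given, else by first appearance.  ``include_zero=False`` drops
    zero-weight edges before export.
    """
    df = ccr_values.dropna(subset=["ccr_pct"]).copy()
    df["weight"] = df["ccr_pct"] / 10.0
    if tag_order is not None:
        rank = {t: k for k, t in enumerate(tag_order)}
        swap = df["tag_i"].map(rank) > df["tag_j"].map(rank)
        df.loc[swap, ["tag_i", "tag_j"]] = df.loc[swap, ["tag_j", "tag_i"]].to_numpy()
        df = df.sort_values(
            by=["tag_i", "tag_j"], key=lambda s: s.map(rank), kind="stable"
        )
    if not include_zero:
        df = df[df["weight"] > 0]
    out = df[["tag_i", "tag_j", "weight"]].rename(
        columns={"tag_i": "source", "tag_j": "target"}
    )
    return out.reset_index(drop=True)


def write_edge_tsv(edges: pd.DataFrame, path: str | Path, decimals: int = 4) -> None:
    """Write an edge table as the Cytoscape-importable TSV."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(EDGE_TSV_HEADER + "\n")
        for row in edges.itertuples(index=False):
            fh.write(f"{row.source}\t{row.target}\t{row.weight:.{decimals}f}\n")


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_edge_tsv` back into an edge table."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["source", "target", "weight"]
    return df


def network_summary(edges: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-node strength (sum of incident weights) and graph density.

    Density here is the mean edge weight -- a [0, 10] closeness summary
    for comparing light vs dark windows -- not the unweighted
    edge-count density.
    """
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    strengths = pd.DataFrame(
        [(n, s) for n, s in g.degree(weight="weight")], columns=["node", "strength"]
    )
    density = float(np.mean(edges["weight"])) if len(edges) else 0.0
    return strengths, density
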