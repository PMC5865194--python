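"""Directed competitive-interaction networks.

Nodes are genera; a directed edge aggressor -> submissive carries the count
of face-to-face encounters in which that direction was observed, plus a
display width in points (weight / 2 — the linear map through the printed
anchor widths: 1 observation = 0.5 pt, 16 observations = 8 pt).  Mutual-
aggression events have no single direction and are excluded from edges but
counted on the graph.  Antiparallel edges (i -> j and j -> i) are kept
separately by default; a "net" view collapses each pair to its dominant
direction with the weight difference.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx
import pandas as pd

__all__ = [
    "build_network",
    "net_view",
    "NetworkDiff",
    "diff_networks",
    "export_network",
    "import_network",
    "display_width",
]

EXPORT_FORMATS = ("edgelist", "graphml", "dot")


def display_width(weight: float) -> float:
    """Edge display width in points: weight / 2 (1 -> 0.5 pt, 16 -> 8 pt), unclamped."""
    return weight / 2.0


def build_network(classified_events: pd.DataFrame, forest: str) -> nx.DiGraph:
    """Aggregate classified events into the forest's directed network.

    Only events with one aggressor and one submissive contribute edges; the
    aggressor points at the submissive.  Mutual-aggression events are
    tallied in the graph attribute ``n_mutual_excluded``.  The sum of edge
    weights equals the number of aggressive/submissive events.
    """
    g = nx.DiGraph(forest=forest, n_mutual_excluded=0)
    if len(classified_events) == 0:
        return g
    ev = classified_events
    a_over_b = (ev["role_a"] == "aggressive") & (ev["role_b"] == "submissive")
    b_over_a = (ev["role_b"] == "aggressive") & (ev["role_a"] == "submissive")
    mutual = (ev["role_a"] == "aggressive") & (ev["role_b"] == "aggressive")
    g.graph["n_mutual_excluded"] = int(mutual.sum())

    directed = pd.concat(
        [
            ev.loc[a_over_b, ["genus_a", "genus_b"]].rename(
                columns={"genus_a": "aggressor", "genus_b": "submissive"}
            ),
            ev.loc[b_over_a, ["genus_b", "genus_a"]].rename(
                columns={"genus_b": "aggressor", "genus_a": "submissive"}
            ),
        ],
        ignore_index=True,
    )
    for (src, dst), grp in directed.groupby(["aggressor", "submissive"]):
        w = int(len(grp))
        g.add_edge(src, dst, weight=w, display_width=display_width(w))
    return g


def net_view(g: nx.DiGraph) -> nx.DiGraph:
    """Collapse antiparallel edge pairs to the dominant direction.

    The surviving edge points at the overall submissive genus and carries
    the absolute weight difference; exactly balanced pairs cancel and leave
    no edge.  Lossless per-direction aggregation is the default elsewhere;
    this view mirrors figure conventions that draw one arrow per pair.
    """
    out = nx.DiGraph(**g.graph)
    out.add_nodes_from(g.nodes)
    seen = set()
    for u, v, data in g.edges(data=True):
        if (v, u) in seen or (u, v) in seen:
            continue
        seen.add((u, v))
        w_fwd = data["weight"]
        w_rev = g.edges[v, u]["weight"] if g.has_edge(v, u) else 0
        net = w_fwd - w_rev
        if net > 0:
            out.add_edge(u, v, weight=net, display_width=display_width(net))
        elif net < 0:
            out.add_edge(v, u, weight=-net, display_width=display_width(-net))
    return out


@dataclass
class NetworkDiff:
    """Directed-edge and node set differences between two forests' networks."""

    edges_lost: set[tuple[str, str]]    # in primary only
    edges_gained: set[tuple[str, str]]  # in logged only
    nodes_gained: set[str]              # new arrivals to the logged network
    nodes_lost: set[str]                # present in primary network only


def diff_networks(net_primary: nx.DiGraph, net_logged: nx.DiGraph) -> NetworkDiff:
    ep, el = set(net_primary.edges), set(net_logged.edges)
    np_, nl = set(net_primary.nodes), set(net_logged.nodes)
    return NetworkDiff(
        edges_lost=ep - el,
        edges_gained=el - ep,
        nodes_gained=nl - np_,
        nodes_lost=np_ - nl,
    )


def export_network(g: nx.DiGraph, path: Union[str, Path], fmt: str) -> Path:
    """Write a network as an edge-list TSV, GraphML, or DOT file.

    Edge list and GraphML round-trip through :func:`import_network`; DOT is
    write-only (for rendering).
    """
    path = Path(path)
    if fmt == "edgelist":
        rows = [
            {"aggressor": u, "submissive": v, "weight": d["weight"], "display_width": d["display_width"]}
            for u, v, d in sorted(g.edges(data=True))
        ]
        df = pd.DataFrame(rows, columns=["aggressor", "submissive", "weight", "display_width"])
        df.to_csv(path, sep="\t", index=False)
        # isolated nodes ride along in a companion column-less convention:
        # the edge list alone cannot carry them, so record them as a header comment
        isolated = sorted(set(g.nodes) - {n for e in g.edges for n in e})
        if isolated:
            text = path.read_text(encoding="utf-8")
            path.write_text("# isolated_nodes: " + ",".join(isolated) + "\n" + text, encoding="utf-8")
    elif fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "dot":
        lines = [f'digraph "{g.graph.get("forest", "network")}" {{']
        for n in sorted(g.nodes):
            lines.append(f'  "{n}";')
        for u, v, d in sorted(g.edges(data=True)):
            lines.append(f'  "{u}" -> "{v}" [weight={d["weight"]}, penwidth={d["display_width"]}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {EXPORT_FORMATS}")
    return path


def import_network(path: Union[str, Path], fmt: str) -> nx.DiGraph:
    """Read a network written by :func:`export_network` (edgelist or graphml)."""
    path = Path(path)
    if fmt == "edgelist":
        g = nx.DiGraph()
        text = path.read_text(encoding="utf-8")
        lines = text.splitlines()
        body = []
        for line in lines:
            if line.startswith("# isolated_nodes:"):
                for n in line.split(":", 1)[1].strip().split(","):
                    if n:
                        g.add_node(n)
            else:
                body.append(line)
        df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
        for _, row in df.iterrows():
            g.add_edge(
                str(row["aggressor"]),
                str(row["submissive"]),
                weight=int(row["weight"]),
                display_width=float(row["display_width"]),
            )
        return g
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.DiGraph(**{k: v for k, v in g.graph.items()})
        out.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, weight=int(d["weight"]), display_width=float(d["display_width"]))
        return out
    raise ValueError(f"unknown format {fmt!r}; importable formats are 'edgelist' and 'graphml'")
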