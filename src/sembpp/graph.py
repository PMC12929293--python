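"""Model-network graph: nodes are candidate models sized by BPP, edges link
models whose specifications differ by exactly one modification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .neighborhood import CandidateModel, ModelSet


@dataclass(frozen=True)
class GraphNode:
    name: str
    bpp: float
    size: float
    labeled: bool


@dataclass
class ModelGraph:
    nodes: list[GraphNode]
    edges: list[tuple[str, str]]
    layout_hint: str = "neato"
    arrow_max_width: float = 2.0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.name, bpp=node.bpp, size=node.size, labeled=node.labeled)
        g.add_edges_from(self.edges)
        return g


def one_modification_apart(a: CandidateModel, b: CandidateModel) -> bool:
    """True when the free-parameter tables differ by exactly one entry."""
    return len(a.free_key_set() ^ b.free_key_set()) == 1


def build_graph(
    model_set: ModelSet,
    min_size: float = 0.5,
    max_size: float = 2.0,
    min_bpp_labeled: float = 0.0,
    arrow_max_width: float = 2.0,
) -> ModelGraph:
    """Build the model-network graph of a fitted model set.

    Node size is a linear rescaling of BPP into [min_size, max_size]; when
    all BPPs are equal every node gets max_size.  Labels are suppressed for
    models with BPP below ``min_bpp_labeled``.
    """
    if not model_set.candidates:
        raise ValueError("empty model set")
    if model_set.bpp_result is None:
        model_set.set_priors(None)
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    bpps = {c.name: model_set.bpp_result.bpp.get(c.name, 0.0) for c in model_set.candidates}
    lo, hi = min(bpps.values()), max(bpps.values())
    nodes = []
    for cand in model_set.candidates:
        b = bpps[cand.name]
        if hi > lo:
            size = min_size + (max_size - min_size) * (b - lo) / (hi - lo)
        else:
            size = max_size
        nodes.append(GraphNode(cand.name, b, size, labeled=b >= min_bpp_labeled))
    edges = []
    cands = model_set.candidates
    for i, a in enumerate(cands):
        for b in cands[i + 1:]:
            if one_modification_apart(a, b):
                pair = tuple(sorted((a.name, b.name)))
                edges.append(pair)
    edges.sort()
    return ModelGraph(nodes=nodes, edges=edges, arrow_max_width=arrow_max_width)


def _dot_escape(name: str) -> str:
    return '"' + name.replace('"', r'\"') + '"'


def export_dot(graph: ModelGraph) -> str:
    """Deterministic DOT text with node width/height set by the BPP scaling
    and edge penwidth scaled by the larger endpoint BPP."""
    lines = ["graph models {", f"  layout={graph.layout_hint};", "  node [shape=circle, fixedsize=true];"]
    bpp_by_name = {n.name: n.bpp for n in graph.nodes}
    max_bpp = max((n.bpp for n in graph.nodes), default=1.0) or 1.0
    for node in sorted(graph.nodes, key=lambda n: n.name):
        label = node.name if node.labeled else ""
        lines.append(
            f"  {_dot_escape(node.name)} [width={node.size:.4f}, height={node.size:.4f}, "
            f'label="{label}", bpp={node.bpp:.6f}];'
        )
    for a, b in sorted(graph.edges):
        pen = graph.arrow_max_width * max(bpp_by_name.get(a, 0.0), bpp_by_name.get(b, 0.0)) / max_bpp
        lines.append(f"  {_dot_escape(a)} -- {_dot_escape(b)} [penwidth={pen:.4f}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
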