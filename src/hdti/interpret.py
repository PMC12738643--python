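"""Attention extraction and export for molecular interpretation.

The attention coefficients depend on the input graph, so they are
captured during an eval-mode forward pass rather than read off the
layer parameters. Per destination node and head they sum to 1 over the
incoming edges (self-loop included). For bond-level interpretation the
self-loop weights are excluded from the min-max normalization but kept
in the map; on export the two directions of each bond are merged by
averaging their weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .chem_graph import MolecularGraph
from .gnn_core import GATv2Layer
from .model import GraphBatch, HybridGNN

__all__ = [
    "AttentionMap",
    "extract_attention",
    "normalize_attention",
    "export_attention_graph",
]


@dataclass
class AttentionMap:
    """Per-edge attention of one molecule at one GAT layer.

    ``edge_index`` includes the attention self-loops; ``is_self_loop``
    flags them. ``raw`` holds the head-aggregated softmax weights;
    ``normalized`` is filled by :func:`normalize_attention` (min-max over
    bond edges only).
    """

    smiles: str
    edge_index: np.ndarray  # [2, E] incl. self-loops
    is_self_loop: np.ndarray  # [E] bool
    raw: np.ndarray  # [E]
    per_head: np.ndarray  # [E, heads]
    layer: int
    head: int | str
    normalized: np.ndarray | None = None


def extract_attention(model: HybridGNN, graph: MolecularGraph,
                      layer: int | str = "last",
                      head: int | str = "mean") -> AttentionMap:
    """Run the graph through the model and capture attention at one
    GAT layer.

    ``layer`` is an index into the hidden stack (or "last" for the final
    GAT layer); indexing a GCN layer is an error. ``head`` selects one
    head or "mean" to average heads.
    """
    gat_idx = model.gat_layer_indices
    if not gat_idx:
        raise ValueError("model has no GAT layers")
    if layer == "last":
        layer = gat_idx[-1]
    layer = int(layer)
    if layer not in gat_idx:
        raise ValueError(
            f"hidden layer {layer} is not a GAT layer; GAT layers are {gat_idx}"
        )
    batch = GraphBatch.from_graphs([graph], np.zeros(1))
    model.forward(batch, training=False)
    target: GATv2Layer = model.hidden_layers[layer]
    ei, alpha, n_real = target.last_attention
    if head == "mean":
        agg = alpha.mean(axis=1)
    else:
        agg = alpha[:, int(head)]
    is_loop = np.zeros(ei.shape[1], dtype=bool)
    is_loop[n_real:] = True
    return AttentionMap(
        smiles=graph.smiles,
        edge_index=ei.copy(),
        is_self_loop=is_loop,
        raw=agg.copy(),
        per_head=alpha.copy(),
        layer=layer,
        head=head,
    )


def normalize_attention(amap: AttentionMap) -> AttentionMap:
    """Min-max rescale the bond-edge weights to [0, 1].

    Self-loop weights are excluded from the scaling (they stay raw in
    ``per_head``/``raw``); constant bond weights map to 0.5. Idempotent
    on the normalized values.
    """
    norm = np.empty_like(amap.raw)
    bond = ~amap.is_self_loop
    vals = amap.raw[bond]
    if vals.size:
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            norm[bond] = (vals - lo) / (hi - lo)
        else:
            norm[bond] = 0.5
    norm[amap.is_self_loop] = np.nan
    return replace(amap, normalized=norm)


def _merged_bond_weights(graph: MolecularGraph, amap: AttentionMap,
                         use_normalized: bool):
    weights = amap.normalized if use_normalized else amap.raw
    if weights is None:
        raise ValueError("map has no normalized weights; "
                         "call normalize_attention first")
    bond = ~amap.is_self_loop
    if int(bond.sum()) != graph.num_edges:
        raise ValueError(
            f"attention map has {int(bond.sum())} bond edges, "
            f"graph has {graph.num_edges}"
        )
    acc: dict[tuple[int, int], list[float]] = {}
    src, dst = amap.edge_index
    for e in np.flatnonzero(bond):
        key = (min(src[e], dst[e]), max(src[e], dst[e]))
        acc.setdefault(key, []).append(float(weights[e]))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def export_attention_graph(graph: MolecularGraph, amap: AttentionMap,
                           path, fmt: str = "graphml",
                           use_normalized: bool = True) -> None:
    """Write the molecule as an attributed graph with per-bond weights.

    One node per atom (label = element symbol), one undirected edge per
    bond whose ``weight`` attribute averages the two directed attention
    weights. ``fmt`` is "graphml" or "dot".
    """
    if fmt not in ("graphml", "dot"):
        raise ValueError(f"format must be 'graphml' or 'dot', got {fmt!r}")
    merged = _merged_bond_weights(graph, amap, use_normalized)
    g = nx.Graph()
    for i in range(graph.num_nodes):
        sym = graph.atom_symbols[i] if graph.atom_symbols else "?"
        g.add_node(i, label=sym, element=sym)
    for (u, v), w in sorted(merged.items()):
        g.add_edge(int(u), int(v), weight=w)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            fh.write("graph attention {\n")
            for i, data in g.nodes(data=True):
                fh.write(f'  n{i} [label="{data["label"]}"];\n')
            for u, v, data in g.edges(data=True):
                fh.write(f'  n{u} -- n{v} [weight={data["weight"]:.6f}];\n')
            fh.write("}\n")
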