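"""Merge per-source intermediate graphs into one warehouse graph.

The merge is a disjoint union: nothing is deduplicated (that is exclusively
the mapper's job). To keep per-source schemas separable, every node label is
rewritten to ``<source_id>_<label>``; edge labels stay readable but every
element carries the originating source id under the reserved provenance key
``__datasource``. A stable external id (``__source_id``) is attached so that
elements can be tracked across GraphML write/read boundaries, where internal
ids are regenerated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Tuple, Union

from . import meta_graph
from .errors import ValidationError
from .property_graph import PropertyGraph, write_graphml
from .workspace import MERGED_STATS_FILE, Workspace

PROVENANCE_KEY = "__datasource"
SOURCE_ID_KEY = "__source_id"

GraphsInput = Union[Mapping[str, PropertyGraph], Iterable[Tuple[str, PropertyGraph]]]


def merge(graphs: GraphsInput) -> PropertyGraph:
    """Disjoint union of per-source graphs with namespaced node labels.

    Input graphs are not modified. The result is deterministic for a given
    source ordering; any permutation of sources yields an isomorphic graph.
    """
    items = list(graphs.items()) if isinstance(graphs, Mapping) else list(graphs)
    seen = set()
    for source_id, _ in items:
        if source_id in seen:
            raise ValidationError(f"duplicate data source id {source_id!r} in merge input")
        seen.add(source_id)

    merged = PropertyGraph()
    for source_id, graph in items:
        node_map: dict[int, int] = {}
        for index, node in enumerate(graph.nodes()):
            props = dict(node.properties)
            props[PROVENANCE_KEY] = source_id
            props[SOURCE_ID_KEY] = f"{source_id}:n{index}"
            new = merged.add_node(f"{source_id}_{node.label}", props)
            node_map[node.node_id] = new.node_id
        for index, edge in enumerate(graph.edges()):
            props = dict(edge.properties)
            props[PROVENANCE_KEY] = source_id
            props[SOURCE_ID_KEY] = f"{source_id}:e{index}"
            merged.add_edge(node_map[edge.from_id], node_map[edge.to_id], edge.label, props)
    return merged


def write_merged(workspace: Workspace, merged: PropertyGraph) -> Path:
    """Write the merged graph (plus its meta-graph statistics) into the
    workspace ``sources`` folder; returns the GraphML path."""
    destination = workspace.merged_graph_path
    write_graphml(merged, destination)
    meta_graph.write_statistics(
        meta_graph.compute_meta_graph(merged),
        workspace.sources_dir / MERGED_STATS_FILE,
    )
    return destination
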