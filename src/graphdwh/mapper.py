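"""The non-destructive mapping meta-layer.

Mapping proceeds in two stages on the merged warehouse graph:

1. **Node mapping.** For every source node its describer can describe, a
   mapping node is created carrying a canonical entity label (``Drug``,
   ``Gene``, ...) and the node's global identifiers. Mapping nodes of the
   same entity label whose identifier sets overlap are collapsed — the
   collapsed partition is exactly the connected components of the
   shared-identifier graph, computed here with a union-find over identifier
   occurrences. Collapse never crosses entity labels: a Drug and a Chemical
   sharing an identifier value stay distinct.

2. **Path mapping.** Each source declares label paths (alternating node and
   edge labels) worth projecting. Concrete simple paths matching a declared
   pattern — all elements from the declaring source, edges followed in their
   stored direction — whose terminal nodes both have mapping nodes yield one
   mapping edge between those mapping nodes, labeled as the describer says
   and annotated with the source id. Multiple sources contributing the same
   relationship appear as parallel mapping edges (one per source), which is
   what enables consensus analysis; multiple concrete paths from the *same*
   source between the same mapping nodes are deduplicated to one edge.

The layer only ever adds elements: every node, edge and property of the
merged graph is preserved unchanged in the mapped graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Mapping, Optional, Sequence

from . import meta_graph
from .datasource import (
    DataSourceRegistry,
    GlobalIdentifier,
    LabelPath,
    MappingDescriber,
)
from .errors import MergedGraphMissingError, ValidationError
from .merger import PROVENANCE_KEY
from .property_graph import Edge, Node, PropertyGraph, read_graphml, write_graphml
from .workspace import MAPPED_STATS_FILE, Workspace

log = logging.getLogger(__name__)

#: Reserved label prefix distinguishing mapping nodes from source nodes.
MAPPING_LABEL_PREFIX = "MAPPED_"
#: Label of the member links connecting a source node to its mapping node.
MEMBER_EDGE_LABEL = "MAPPED_TO"
#: Marker property present on every meta-layer element.
MAPPED_MARKER_KEY = "__mapped"
#: Property on mapping nodes holding the sorted "TYPE:value" identifier list.
IDENTIFIERS_KEY = "ids"

#: Guard against pathological path declarations; longer paths are refused.
DEFAULT_MAX_PATH_LABELS = 10


@dataclass(frozen=True)
class ConcretePath:
    """A concrete match of a :class:`LabelPath`: alternating nodes and edges.

    Node labels are the source's own (merged-graph prefix stripped); node and
    edge ids refer to the merged graph.
    """

    nodes: tuple[Node, ...]
    edges: tuple[Edge, ...]


# -- collapse --------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def collapse_overlaps(
    identifier_sets: Sequence[AbstractSet[GlobalIdentifier]],
) -> list[list[int]]:
    """Partition mapping-node candidates by transitive identifier overlap.

    Returns groups of input indices: two candidates end up in the same group
    exactly when they are connected in the graph whose links join candidates
    sharing at least one identifier. Groups are ordered by their smallest
    member index, members ascending — so the result is independent of the
    processing order of equal inputs.
    """
    uf = _UnionFind(len(identifier_sets))
    first_owner: dict[GlobalIdentifier, int] = {}
    for index, identifiers in enumerate(identifier_sets):
        for identifier in identifiers:
            owner = first_owner.setdefault(identifier, index)
            if owner != index:
                uf.union(owner, index)
    groups: dict[int, list[int]] = {}
    for index in range(len(identifier_sets)):
        groups.setdefault(uf.find(index), []).append(index)
    return [groups[root] for root in sorted(groups)]


# -- node mapping ----------------------------------------------------------


def _strip_prefix(label: str, source_id: str) -> str:
    prefix = f"{source_id}_"
    return label[len(prefix):] if label.startswith(prefix) else label


def create_mapping_nodes(
    merged: PropertyGraph, describers: Mapping[str, MappingDescriber]
) -> PropertyGraph:
    """Add mapping nodes (already collapsed) and member links to ``merged``.

    ``describers`` maps data-source ids to their describers; describer
    exceptions are logged and isolated to the offending node. The merged
    graph's pre-existing elements are never touched. Returns ``merged``.
    """
    descriptions: list[tuple[int, str, frozenset[GlobalIdentifier]]] = []
    for source_id, describer in describers.items():
        for label in sorted(describer.describable_node_labels):
            for node in merged.find_nodes(f"{source_id}_{label}"):
                view = Node(node.node_id, label, node.properties)
                try:
                    description = describer.describe_node(view)
                except Exception as exc:
                    log.warning(
                        "describer of %s failed on node %s (%s): %s",
                        source_id, node.node_id, label, exc,
                    )
                    continue
                if description is None:
                    continue
                descriptions.append(
                    (node.node_id, description.mapped_label, frozenset(description.identifiers))
                )

    by_label: dict[str, list[tuple[int, frozenset[GlobalIdentifier]]]] = {}
    for node_id, mapped_label, identifiers in descriptions:
        by_label.setdefault(mapped_label, []).append((node_id, identifiers))

    for mapped_label, entries in by_label.items():
        for group in collapse_overlaps([ids for _, ids in entries]):
            union_ids = sorted(str(i) for i in frozenset().union(*(entries[g][1] for g in group)))
            mapping_node = merged.add_node(
                MAPPING_LABEL_PREFIX + mapped_label,
                {IDENTIFIERS_KEY: union_ids, MAPPED_MARKER_KEY: True},
            )
            for index in group:
                merged.add_edge(
                    entries[index][0], mapping_node, MEMBER_EDGE_LABEL,
                    {MAPPED_MARKER_KEY: True},
                )
    return merged


def mapping_membership(graph: PropertyGraph) -> dict[int, int]:
    """source node id → mapping node id, recovered from the member links."""
    return {
        edge.from_id: edge.to_id for edge in graph.find_edges(MEMBER_EDGE_LABEL)
    }


def mapping_nodes(graph: PropertyGraph) -> list[Node]:
    """All mapping nodes of the meta-layer, in insertion order."""
    return [
        node for node in graph.nodes()
        if node.label.startswith(MAPPING_LABEL_PREFIX) and node.get(MAPPED_MARKER_KEY)
    ]


def mapping_edges(graph: PropertyGraph) -> list[Edge]:
    """All projected relationship edges of the meta-layer (member links excluded)."""
    return [
        edge for edge in graph.edges()
        if edge.get(MAPPED_MARKER_KEY) and edge.label != MEMBER_EDGE_LABEL
    ]


# -- path matching ---------------------------------------------------------


def find_paths(
    graph: PropertyGraph,
    label_path: LabelPath,
    source_id: Optional[str] = None,
    max_labels: int = DEFAULT_MAX_PATH_LABELS,
) -> list[ConcretePath]:
    """All simple concrete paths matching ``label_path``, in deterministic
    (node/edge insertion) order.

    With ``source_id`` given, node labels are matched against their
    source-prefixed form and every element must carry that source's
    provenance — a path never mixes sources. Edges are traversed in their
    stored direction only; a path never revisits a node. Meta-layer edges
    are never part of a concrete path.
    """
    if not isinstance(label_path, LabelPath):
        label_path = LabelPath(label_path)
    if len(label_path) > max_labels:
        raise ValidationError(
            f"label path with {len(label_path)} labels exceeds the maximum of {max_labels}"
        )
    node_labels, edge_labels = label_path.node_labels, label_path.edge_labels

    def graph_label(position: int) -> str:
        return f"{source_id}_{node_labels[position]}" if source_id else node_labels[position]

    results: list[ConcretePath] = []

    def extend(nodes: list[Node], edges: list[Edge], depth: int) -> None:
        if depth == len(edge_labels):
            results.append(ConcretePath(tuple(nodes), tuple(edges)))
            return
        visited = {n.node_id for n in nodes}
        for edge in graph.out_edges(nodes[-1].node_id):
            if edge.label != edge_labels[depth] or edge.get(MAPPED_MARKER_KEY):
                continue
            if source_id is not None and edge.get(PROVENANCE_KEY) != source_id:
                continue
            target = graph.node(edge.to_id)
            if target.label != graph_label(depth + 1) or target.node_id in visited:
                continue
            view = Node(target.node_id, node_labels[depth + 1], target.properties)
            extend(nodes + [view], edges + [edge], depth + 1)

    for start in graph.find_nodes(graph_label(0)):
        view = Node(start.node_id, node_labels[0], start.properties)
        extend([view], [], 0)
    return results


# -- path mapping ----------------------------------------------------------


def map_paths(
    merged: PropertyGraph,
    describers: Mapping[str, MappingDescriber],
    membership: Optional[dict[int, int]] = None,
) -> PropertyGraph:
    """Project declared label paths onto mapping edges.

    Only paths whose two terminal nodes both have mapping nodes produce an
    edge; at most one mapping edge is created per (from, to, label, source).
    Returns ``merged``.
    """
    if membership is None:
        membership = mapping_membership(merged)
    created: set[tuple[int, int, str, str]] = set()
    for source_id, describer in describers.items():
        for declared in describer.describable_paths:
            for path in find_paths(merged, declared, source_id):
                from_mapping = membership.get(path.nodes[0].node_id)
                to_mapping = membership.get(path.nodes[-1].node_id)
                if from_mapping is None or to_mapping is None:
                    continue
                try:
                    description = describer.describe_path(path)
                except Exception as exc:
                    log.warning("path describer of %s failed: %s", source_id, exc)
                    continue
                if description is None:
                    continue
                key = (from_mapping, to_mapping, description.mapped_relationship_label, source_id)
                if key in created:
                    continue
                created.add(key)
                merged.add_edge(
                    from_mapping, to_mapping, description.mapped_relationship_label,
                    {PROVENANCE_KEY: source_id, MAPPED_MARKER_KEY: True},
                )
    return merged


def build_mapping_layer(
    merged: PropertyGraph, describers: Mapping[str, MappingDescriber]
) -> PropertyGraph:
    """Node mapping followed by path mapping, in place."""
    create_mapping_nodes(merged, describers)
    map_paths(merged, describers)
    return merged


def run_mapping(workspace: Workspace, registry: DataSourceRegistry) -> Path:
    """Read the merged graph, add the mapping layer, write the mapped graph.

    The merged GraphML file is never modified. Unresolvable source ids are
    skipped (their nodes simply stay unmapped).
    """
    merged_path = workspace.merged_graph_path
    if not merged_path.is_file():
        raise MergedGraphMissingError(
            f"no merged graph at {merged_path}; run the update/merge step first"
        )
    graph = read_graphml(merged_path)
    describers = {
        source_id: registry.resolve(source_id).mapping_describer
        for source_id in workspace.config.data_source_ids
        if source_id in registry
    }
    build_mapping_layer(graph, describers)
    destination = workspace.mapped_graph_path
    write_graphml(graph, destination)
    meta_graph.write_statistics(
        meta_graph.compute_meta_graph(graph),
        workspace.sources_dir / MAPPED_STATS_FILE,
    )
    return destination
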