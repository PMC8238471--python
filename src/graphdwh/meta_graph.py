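"""Label-level meta graphs and their plain-text statistics reports.

A meta graph condenses a property graph to its schema: how many nodes carry
each label, and how many edges realise each (from-label, edge-label,
to-label) triple. The counts always sum to the underlying graph's node and
edge totals, and the meta graph of a disjoint union is the entrywise sum of
the parts — both properties are exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .property_graph import PropertyGraph


@dataclass
class MetaGraph:
    node_counts: dict[str, int] = field(default_factory=dict)
    edge_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    @property
    def total_nodes(self) -> int:
        return sum(self.node_counts.values())

    @property
    def total_edges(self) -> int:
        return sum(self.edge_counts.values())


def compute_meta_graph(graph: PropertyGraph) -> MetaGraph:
    """Tally node labels and (from, edge, to) label triples, entries sorted
    label-lexicographically."""
    node_counts: dict[str, int] = {}
    edge_counts: dict[tuple[str, str, str], int] = {}
    for node in graph.nodes():
        node_counts[node.label] = node_counts.get(node.label, 0) + 1
    for edge in graph.edges():
        triple = (graph.node(edge.from_id).label, edge.label, graph.node(edge.to_id).label)
        edge_counts[triple] = edge_counts.get(triple, 0) + 1
    return MetaGraph(
        dict(sorted(node_counts.items())),
        dict(sorted(edge_counts.items())),
    )


def format_statistics(meta: MetaGraph) -> str:
    """Fixed-width report; stable line order so regeneration is byte-identical."""
    lines = ["Meta graph statistics", "=" * 21, ""]
    lines.append(f"Node labels: {len(meta.node_counts)} ({meta.total_nodes} nodes total)")
    name_width = max(
        [len(label) for label in meta.node_counts]
        + [len(_triple_text(t)) for t in meta.edge_counts]
        + [1]
    )
    for label in sorted(meta.node_counts):
        lines.append(f"  {label.ljust(name_width)}  {meta.node_counts[label]:>8d}")
    lines.append("")
    lines.append(f"Edge label paths: {len(meta.edge_counts)} ({meta.total_edges} edges total)")
    for triple in sorted(meta.edge_counts):
        lines.append(f"  {_triple_text(triple).ljust(name_width)}  {meta.edge_counts[triple]:>8d}")
    lines.append("")
    return "\n".join(lines)


def _triple_text(triple: tuple[str, str, str]) -> str:
    from_label, edge_label, to_label = triple
    return f"{from_label} -[{edge_label}]-> {to_label}"


def write_statistics(meta: MetaGraph, destination: Union[str, Path]) -> None:
    Path(destination).write_text(format_statistics(meta), encoding="utf-8")
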