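"""In-memory labeled property graph with GraphML serialization.

The property graph is the universal currency of every pipeline stage: data
source exporters produce one per source, the merger combines them, and the
mapper adds the meta-layer on top. Nodes carry exactly one label (an entity
category such as ``"Drug"`` or ``"Gene"``); edges are directed, carry one
label (a relationship type such as ``"TARGETS"``), and parallel edges with
identical endpoints and label are permitted. Properties are maps from string
keys to scalars (bool, int, float, str) or homogeneous non-empty lists
thereof — the set that survives a GraphML round-trip.

GraphML dialect
---------------
GraphML has no native list type, so list values are encoded as
delimiter-joined strings (delimiter ``|``, items escaped with ``\\``) and the
``<key>`` declaration carries an ``attr.list="true"`` marker. The node label
is stored under the reserved attribute ``labels``, the edge label under
``label``. Keys are declared in first-occurrence order and elements are
serialized in insertion order, so repeated exports of the same graph are
byte-identical — a property the pipeline's fixed-point checks rely on.

Internal numeric ids are regenerated on read (in document order); any module
that needs stable identity across a write/read boundary must store it in a
property (the merger uses ``__source_id``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

from lxml import etree

from .errors import GraphMLError, ValidationError

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
NODE_LABEL_ATTR = "labels"
EDGE_LABEL_ATTR = "label"
LIST_DELIMITER = "|"
LIST_ESCAPE = "\\"

_HEADER_COMMENT = (
    " Property lists are encoded as '" + LIST_DELIMITER + "'-delimited strings "
    "(items escaped with '" + LIST_ESCAPE + "'); list-valued keys carry "
    'attr.list="true". Node labels are stored under the attribute "labels", '
    'edge labels under "label". '
)

Scalar = Union[bool, int, float, str]
PropertyValue = Union[Scalar, list]
PropertyMap = Mapping[str, PropertyValue]


@dataclass
class Node:
    node_id: int
    label: str
    properties: dict

    def __getitem__(self, key: str) -> PropertyValue:
        return self.properties[key]

    def get(self, key: str, default=None):
        return self.properties.get(key, default)


@dataclass
class Edge:
    edge_id: int
    from_id: int
    to_id: int
    label: str
    properties: dict

    def get(self, key: str, default=None):
        return self.properties.get(key, default)


def _validate_label(label: str) -> None:
    if not isinstance(label, str) or not label:
        raise ValidationError(f"label must be a non-empty string, got {label!r}")


def _validate_properties(properties: PropertyMap) -> dict:
    validated = {}
    for key, value in properties.items():
        if not isinstance(key, str) or not key:
            raise ValidationError(f"property key must be a non-empty string, got {key!r}")
        if isinstance(value, list):
            if not value:
                raise ValidationError(f"property {key!r}: empty lists are not serializable")
            first_type = _scalar_type(value[0], key)
            for item in value[1:]:
                if _scalar_type(item, key) != first_type:
                    raise ValidationError(f"property {key!r}: list values must be homogeneous")
            validated[key] = list(value)
        else:
            _scalar_type(value, key)
            validated[key] = value
    return validated


def _scalar_type(value, key: str) -> type:
    # bool is a subclass of int; check it first so True is not typed as long
    for typ in (bool, int, float, str):
        if isinstance(value, typ):
            return typ
    raise ValidationError(
        f"property {key!r}: unsupported value type {type(value).__name__} ({value!r})"
    )


def _index_key(key: str, value: PropertyValue):
    return (key, tuple(value)) if isinstance(value, list) else (key, value)


class PropertyGraph:
    """Mutable labeled property graph with label and property indices."""

    def __init__(self) -> None:
        self._nodes: dict[int, Node] = {}
        self._edges: dict[int, Edge] = {}
        self._next_node_id = 0
        self._next_edge_id = 0
        self._nodes_by_label: dict[str, list[int]] = {}
        self._edges_by_label: dict[str, list[int]] = {}
        self._nodes_by_property: dict[tuple, list[int]] = {}
        self._out_edges: dict[int, list[int]] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, label: str, properties: Optional[PropertyMap] = None) -> Node:
        _validate_label(label)
        props = _validate_properties(properties or {})
        node = Node(self._next_node_id, label, props)
        self._next_node_id += 1
        self._nodes[node.node_id] = node
        self._nodes_by_label.setdefault(label, []).append(node.node_id)
        for key, value in props.items():
            self._nodes_by_property.setdefault(_index_key(key, value), []).append(node.node_id)
        self._out_edges[node.node_id] = []
        return node

    def add_edge(
        self,
        from_node: Union[Node, int],
        to_node: Union[Node, int],
        label: str,
        properties: Optional[PropertyMap] = None,
    ) -> Edge:
        _validate_label(label)
        from_id = from_node.node_id if isinstance(from_node, Node) else from_node
        to_id = to_node.node_id if isinstance(to_node, Node) else to_node
        for endpoint in (from_id, to_id):
            if endpoint not in self._nodes:
                raise ValidationError(f"edge endpoint {endpoint!r} does not exist in the graph")
        props = _validate_properties(properties or {})
        edge = Edge(self._next_edge_id, from_id, to_id, label, props)
        self._next_edge_id += 1
        self._edges[edge.edge_id] = edge
        self._edges_by_label.setdefault(label, []).append(edge.edge_id)
        self._out_edges[from_id].append(edge.edge_id)
        return edge

    # -- access -----------------------------------------------------------

    @property
    def node_count(self) -> int:
        return len(self._nodes)

    @property
    def edge_count(self) -> int:
        return len(self._edges)

    def nodes(self) -> Iterator[Node]:
        """Nodes in insertion order."""
        return iter(self._nodes.values())

    def edges(self) -> Iterator[Edge]:
        """Edges in insertion order."""
        return iter(self._edges.values())

    def node(self, node_id: int) -> Node:
        return self._nodes[node_id]

    def edge(self, edge_id: int) -> Edge:
        return self._edges[edge_id]

    def has_node(self, node_id: int) -> bool:
        return node_id in self._nodes

    def out_edges(self, node_id: int) -> list[Edge]:
        """Outgoing edges of a node, in insertion order."""
        return [self._edges[eid] for eid in self._out_edges[node_id]]

    def find_nodes(
        self, label: str, property_filter: Optional[PropertyMap] = None
    ) -> list[Node]:
        """Nodes matching ``label`` and every filter entry, in insertion order."""
        ids: Iterable[int] = self._nodes_by_label.get(label, [])
        if property_filter:
            for key, value in property_filter.items():
                matching = set(self._nodes_by_property.get(_index_key(key, value), ()))
                ids = [i for i in ids if i in matching]
        return [self._nodes[i] for i in ids]

    def find_edges(self, label: Optional[str] = None) -> list[Edge]:
        if label is None:
            return list(self._edges.values())
        return [self._edges[i] for i in self._edges_by_label.get(label, [])]

    def node_labels(self) -> list[str]:
        """Distinct node labels in first-use order."""
        return list(self._nodes_by_label)


# -- structural equality ---------------------------------------------------


def graphs_equal(a: PropertyGraph, b: PropertyGraph) -> bool:
    """Structural equality up to internal id relabeling.

    Nodes and edges are compared position-wise in insertion order, with edge
    endpoints compared through the positional id mapping. This is exactly the
    equality preserved by a GraphML round-trip.
    """
    if a.node_count != b.node_count or a.edge_count != b.edge_count:
        return False
    a_nodes, b_nodes = list(a.nodes()), list(b.nodes())
    a_pos = {n.node_id: i for i, n in enumerate(a_nodes)}
    b_pos = {n.node_id: i for i, n in enumerate(b_nodes)}
    for na, nb in zip(a_nodes, b_nodes):
        if na.label != nb.label or na.properties != nb.properties:
            return False
    for ea, eb in zip(a.edges(), b.edges()):
        if ea.label != eb.label or ea.properties != eb.properties:
            return False
        if a_pos[ea.from_id] != b_pos[eb.from_id] or a_pos[ea.to_id] != b_pos[eb.to_id]:
            return False
    return True


# -- GraphML serialization -------------------------------------------------

_TYPE_NAMES = {bool: "boolean", int: "long", float: "double", str: "string"}
_TYPE_FOR_NAME = {"boolean": bool, "int": int, "long": int, "float": float,
                  "double": float, "string": str}


@dataclass
class _KeyDecl:
    key_id: str
    domain: str  # "node" | "edge"
    name: str
    scalar: type
    is_list: bool = False


def _infer_key(domain: str, name: str, value: PropertyValue) -> tuple[type, bool]:
    if isinstance(value, list):
        return _scalar_type(value[0], name), True
    return _scalar_type(value, name), False


def _encode_scalar(value: Scalar) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _escape_item(text: str) -> str:
    return text.replace(LIST_ESCAPE, LIST_ESCAPE * 2).replace(
        LIST_DELIMITER, LIST_ESCAPE + LIST_DELIMITER
    )


def _encode_value(value: PropertyValue) -> str:
    if isinstance(value, list):
        return LIST_DELIMITER.join(_escape_item(_encode_scalar(v)) for v in value)
    return _encode_scalar(value)


def _decode_scalar(text: str, scalar: type):
    if scalar is bool:
        return text == "true"
    if scalar is int:
        return int(text)
    if scalar is float:
        return float(text)
    return text


def _split_list(text: str) -> list[str]:
    items, current, i = [], [], 0
    while i < len(text):
        ch = text[i]
        if ch == LIST_ESCAPE and i + 1 < len(text):
            current.append(text[i + 1])
            i += 2
        elif ch == LIST_DELIMITER:
            items.append("".join(current))
            current = []
            i += 1
        else:
            current.append(ch)
            i += 1
    items.append("".join(current))
    return items


def _decode_value(text: str, scalar: type, is_list: bool):
    if is_list:
        return [_decode_scalar(item, scalar) for item in _split_list(text)]
    return _decode_scalar(text, scalar)


def _collect_keys(graph: PropertyGraph) -> dict[tuple[str, str], _KeyDecl]:
    """Key declarations in first-occurrence order (nodes first, then edges)."""
    decls: dict[tuple[str, str], _KeyDecl] = {}

    def declare(domain: str, name: str, value: PropertyValue) -> None:
        scalar, is_list = _infer_key(domain, name, value)
        existing = decls.get((domain, name))
        if existing is None:
            decls[(domain, name)] = _KeyDecl(f"d{len(decls)}", domain, name, scalar, is_list)
        elif (existing.scalar, existing.is_list) != (scalar, is_list):
            raise ValidationError(
                f"{domain} property {name!r} has inconsistent types across elements "
                f"({existing.scalar.__name__} vs {scalar.__name__})"
            )

    decls[("node", NODE_LABEL_ATTR)] = _KeyDecl("d0", "node", NODE_LABEL_ATTR, str)
    for node in graph.nodes():
        for name, value in node.properties.items():
            declare("node", name, value)
    decls[("edge", EDGE_LABEL_ATTR)] = _KeyDecl(
        f"d{len(decls)}", "edge", EDGE_LABEL_ATTR, str
    )
    for edge in graph.edges():
        for name, value in edge.properties.items():
            declare("edge", name, value)
    return decls


def write_graphml(graph: PropertyGraph, destination: Union[str, Path]) -> None:
    """Serialize ``graph`` as a standards-conformant GraphML document (UTF-8).

    Deterministic: the same graph (same insertion order) always yields
    byte-identical output.
    """
    decls = _collect_keys(graph)
    root = etree.Element("graphml", nsmap={None: GRAPHML_NS})
    root.append(etree.Comment(_HEADER_COMMENT))
    for decl in decls.values():
        key_el = etree.SubElement(root, "key", id=decl.key_id)
        key_el.set("for", decl.domain)
        key_el.set("attr.name", decl.name)
        key_el.set("attr.type", _TYPE_NAMES[decl.scalar])
        if decl.is_list:
            key_el.set("attr.list", "true")
    graph_el = etree.SubElement(root, "graph", id="G", edgedefault="directed")
    for i, node in enumerate(graph.nodes()):
        node_el = etree.SubElement(graph_el, "node", id=f"n{i}")
        _data(node_el, decls[("node", NODE_LABEL_ATTR)].key_id, node.label)
        for name, value in node.properties.items():
            _data(node_el, decls[("node", name)].key_id, _encode_value(value))
    positions = {node.node_id: i for i, node in enumerate(graph.nodes())}
    for i, edge in enumerate(graph.edges()):
        edge_el = etree.SubElement(
            graph_el,
            "edge",
            id=f"e{i}",
            source=f"n{positions[edge.from_id]}",
            target=f"n{positions[edge.to_id]}",
        )
        _data(edge_el, decls[("edge", EDGE_LABEL_ATTR)].key_id, edge.label)
        for name, value in edge.properties.items():
            _data(edge_el, decls[("edge", name)].key_id, _encode_value(value))
    payload = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    Path(destination).write_bytes(payload)


def _data(parent, key_id: str, text: str) -> None:
    el = etree.SubElement(parent, "data", key=key_id)
    el.text = text


def read_graphml(source: Union[str, Path]) -> PropertyGraph:
    """Parse a GraphML document written by :func:`write_graphml`.

    Internal ids are regenerated in document order; a malformed document
    raises :class:`GraphMLError` and no partial graph is returned.
    """
    try:
        tree = etree.parse(str(source))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise GraphMLError(f"cannot parse GraphML from {source}: {exc}") from exc
    root = tree.getroot()
    ns = {"g": GRAPHML_NS}
    decls: dict[str, _KeyDecl] = {}
    for key_el in root.findall("g:key", ns):
        type_name = key_el.get("attr.type", "string")
        if type_name not in _TYPE_FOR_NAME:
            raise GraphMLError(f"unknown attribute type {type_name!r} in {source}")
        decls[key_el.get("id")] = _KeyDecl(
            key_el.get("id"),
            key_el.get("for", "node"),
            key_el.get("attr.name"),
            _TYPE_FOR_NAME[type_name],
            key_el.get("attr.list") == "true",
        )
    graph_el = root.find("g:graph", ns)
    if graph_el is None:
        raise GraphMLError(f"no <graph> element in {source}")
    graph = PropertyGraph()
    id_map: dict[str, int] = {}
    for node_el in graph_el.findall("g:node", ns):
        label, props = _read_data(node_el, decls, ns, NODE_LABEL_ATTR, source)
        node = graph.add_node(label, props)
        id_map[node_el.get("id")] = node.node_id
    for edge_el in graph_el.findall("g:edge", ns):
        label, props = _read_data(edge_el, decls, ns, EDGE_LABEL_ATTR, source)
        for attr in ("source", "target"):
            if edge_el.get(attr) not in id_map:
                raise GraphMLError(
                    f"edge {edge_el.get('id')!r} references unknown node "
                    f"{edge_el.get(attr)!r} in {source}"
                )
        graph.add_edge(id_map[edge_el.get("source")], id_map[edge_el.get("target")], label, props)
    return graph


def _read_data(element, decls, ns, label_attr, source):
    label = None
    props: dict = {}
    for data_el in element.findall("g:data", ns):
        key_id = data_el.get("key")
        decl = decls.get(key_id)
        if decl is None:
            raise GraphMLError(f"data references undeclared key {key_id!r} in {source}")
        text = data_el.text or ""
        if decl.name == label_attr:
            label = text
        else:
            props[decl.name] = _decode_value(text, decl.scalar, decl.is_list)
    if not label:
        raise GraphMLError(
            f"element {element.get('id')!r} has no {label_attr!r} attribute in {source}"
        )
    return label, props
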