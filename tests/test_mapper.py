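"""Mapping meta-layer: identifier collapse, path matching, projection."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from graphdwh import (
    GlobalIdentifier,
    LabelPath,
    MappingDescriber,
    NodeMappingDescription,
    PathMappingDescription,
    PropertyGraph,
    build_mapping_layer,
    collapse_overlaps,
    create_mapping_nodes,
    create_workspace,
    find_paths,
    map_paths,
    merge,
    read_graphml,
    run_mapping,
    write_merged,
)
from graphdwh.datasource import DataSourceRegistry
from graphdwh.errors import MergedGraphMissingError, ValidationError
from graphdwh.mapper import (
    MAPPING_LABEL_PREFIX,
    mapping_edges,
    mapping_membership,
    mapping_nodes,
)
from graphdwh.merger import PROVENANCE_KEY
from graphdwh.synthetic import builtin_fixtures

from conftest import build_random_graph


# -- oracles ----------------------------------------------------------------


def collapse_oracle(identifier_sets):
    """Connected components of the shared-identifier graph (networkx)."""
    G = nx.Graph()
    G.add_nodes_from(range(len(identifier_sets)))
    for i in range(len(identifier_sets)):
        for j in range(i + 1, len(identifier_sets)):
            if identifier_sets[i] & identifier_sets[j]:
                G.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(G)}


def path_oracle(graph, labels):
    """Exhaustive simple-path enumeration over a networkx MultiDiGraph."""
    node_labels, edge_labels = labels[0::2], labels[1::2]
    G = nx.MultiDiGraph()
    for n in graph.nodes():
        G.add_node(n.node_id, label=n.label)
    for e in graph.edges():
        G.add_edge(e.from_id, e.to_id, key=e.edge_id, label=e.label)
    hops = len(edge_labels)
    found = set()
    starts = [n.node_id for n in graph.nodes() if n.label == node_labels[0]]
    ends = [n.node_id for n in graph.nodes() if n.label == node_labels[-1]]
    for u in starts:
        for v in ends:
            if u == v:
                continue
            for edge_path in nx.all_simple_edge_paths(G, u, v, cutoff=hops):
                if len(edge_path) != hops:
                    continue
                node_seq = [u] + [edge[1] for edge in edge_path]
                if any(G.nodes[n]["label"] != node_labels[i] for i, n in enumerate(node_seq)):
                    continue
                if any(G.edges[edge]["label"] != edge_labels[i] for i, edge in enumerate(edge_path)):
                    continue
                found.add((tuple(node_seq), tuple(edge[2] for edge in edge_path)))
    return found


def random_identifier_sets(rng, max_sets=40, alphabet=20):
    return [
        frozenset(
            GlobalIdentifier("T", f"v{rng.randrange(alphabet)}")
            for _ in range(rng.randint(1, 4))
        )
        for _ in range(rng.randint(0, max_sets))
    ]


# -- collapse ---------------------------------------------------------------


class TestCollapse:
    def test_disjoint_sets_stay_apart(self):
        a = frozenset({GlobalIdentifier("T", "a")})
        b = frozenset({GlobalIdentifier("T", "b")})
        assert collapse_overlaps([a, b]) == [[0], [1]]

    def test_transitive_chain_collapses(self):
        x, y, z = (GlobalIdentifier("T", v) for v in "xyz")
        groups = collapse_overlaps([frozenset({x}), frozenset({x, y}), frozenset({y, z})])
        assert groups == [[0, 1, 2]]

    def test_idempotent_on_collapsed_layer(self):
        x, y, z = (GlobalIdentifier("T", v) for v in "xyz")
        collapsed = [frozenset({x, y, z}), frozenset({GlobalIdentifier("T", "w")})]
        assert collapse_overlaps(collapsed) == [[0], [1]]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_connected_components_oracle(self, seed):
        rng = random.Random(seed)
        sets = random_identifier_sets(rng)
        got = {frozenset(group) for group in collapse_overlaps(sets)}
        assert got == collapse_oracle(sets)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.frozensets(st.integers(0, 12).map(lambda v: GlobalIdentifier("T", f"v{v}")),
                      min_size=1, max_size=4),
        max_size=25,
    ))
    def test_order_invariant_partition(self, sets):
        forward = {frozenset(g) for g in collapse_overlaps(sets)}
        reversed_sets = list(reversed(sets))
        n = len(sets)
        backward = {
            frozenset(n - 1 - i for i in g) for g in collapse_overlaps(reversed_sets)
        }
        assert forward == backward


# -- node mapping -----------------------------------------------------------


class DictDescriber(MappingDescriber):
    """Describer driven by explicit per-label identifier-property rules."""

    def __init__(self, rules, paths=(), path_labels=None, fail_on=None):
        self._rules = rules          # label -> (mapped_label, [(id_type, prop key)])
        self._paths = tuple(LabelPath(p) for p in paths)
        self._path_labels = path_labels or {}
        self._fail_on = fail_on

    @property
    def describable_node_labels(self):
        return frozenset(self._rules)

    @property
    def describable_paths(self):
        return self._paths

    def describe_node(self, node):
        if self._fail_on and node.get("id") == self._fail_on:
            raise RuntimeError("describer exploded")
        rule = self._rules.get(node.label)
        if rule is None:
            return None
        mapped_label, id_specs = rule
        identifiers = {
            GlobalIdentifier(id_type, node.properties[prop])
            for id_type, prop in id_specs if prop in node.properties
        }
        if not identifiers:
            return None
        return NodeMappingDescription(mapped_label, identifiers)

    def describe_path(self, path):
        labels = tuple(n.label for n in path.nodes) + tuple(e.label for e in path.edges)
        return PathMappingDescription(self._path_labels.get(labels, path.edges[0].label))


class TestCreateMappingNodes:
    def test_single_described_node(self):
        g = PropertyGraph()
        g.add_node("Gene", {"id": "BRCA2", "symbol": "BRCA2"})
        merged = merge({"A": g})
        create_mapping_nodes(
            merged, {"A": DictDescriber({"Gene": ("Gene", [("HGNC_SYMBOL", "symbol")])})}
        )
        nodes = mapping_nodes(merged)
        assert len(nodes) == 1
        assert nodes[0].label == MAPPING_LABEL_PREFIX + "Gene"
        assert nodes[0].properties["ids"] == ["HGNC_SYMBOL:BRCA2"]
        assert len(mapping_membership(merged)) == 1

    def test_undescribed_node_gets_no_mapping_node(self):
        g = PropertyGraph()
        g.add_node("Junk", {"id": "x"})
        merged = merge({"A": g})
        create_mapping_nodes(merged, {"A": DictDescriber({})})
        assert mapping_nodes(merged) == []

    def test_two_sources_sharing_identifier_collapse_to_one(self):
        a, b = PropertyGraph(), PropertyGraph()
        a.add_node("Drug", {"id": "aspirin", "unii": "R16CO5Y76E"})
        b.add_node("Compound", {"id": "ASA", "unii": "R16CO5Y76E"})
        merged = merge({"A": a, "B": b})
        create_mapping_nodes(merged, {
            "A": DictDescriber({"Drug": ("Drug", [("UNII", "unii")])}),
            "B": DictDescriber({"Compound": ("Drug", [("UNII", "unii")])}),
        })
        assert len(mapping_nodes(merged)) == 1
        assert len(mapping_membership(merged)) == 2  # two member links

    def test_same_identifier_different_mapped_labels_not_collapsed(self):
        a = PropertyGraph()
        a.add_node("Drug", {"id": "d", "unii": "X"})
        a.add_node("Chemical", {"id": "c", "unii": "X"})
        merged = merge({"A": a})
        create_mapping_nodes(merged, {
            "A": DictDescriber({
                "Drug": ("Drug", [("UNII", "unii")]),
                "Chemical": ("Chemical", [("UNII", "unii")]),
            })
        })
        assert len(mapping_nodes(merged)) == 2

    def test_describer_exception_isolated_to_node(self):
        g = PropertyGraph()
        g.add_node("Gene", {"id": "GOOD", "symbol": "GOOD"})
        g.add_node("Gene", {"id": "BAD", "symbol": "BAD"})
        merged = merge({"A": g})
        create_mapping_nodes(merged, {
            "A": DictDescriber({"Gene": ("Gene", [("HGNC_SYMBOL", "symbol")])},
                               fail_on="BAD")
        })
        nodes = mapping_nodes(merged)
        assert len(nodes) == 1
        assert nodes[0].properties["ids"] == ["HGNC_SYMBOL:GOOD"]

    def test_original_elements_untouched(self, rng):
        merged = merge({"A": build_random_graph(rng, max_nodes=20)})
        before = [(n.label, dict(n.properties)) for n in merged.nodes()]
        n_edges = merged.edge_count
        create_mapping_nodes(merged, {"A": DictDescriber({"Drug": ("Drug", [("ID", "id")])})})
        after = [(n.label, dict(n.properties)) for n in merged.nodes()][: len(before)]
        assert after == before
        for edge in list(merged.edges())[:n_edges]:
            assert "__mapped" not in edge.properties


# -- path matching ----------------------------------------------------------


class TestFindPaths:
    def test_single_edge_pattern(self):
        g = PropertyGraph()
        d1, d2 = g.add_node("Drug"), g.add_node("Drug")
        s1, s2 = g.add_node("Disease"), g.add_node("Disease")
        g.add_edge(d1, s1, "INDUCES")
        g.add_edge(d2, s2, "INDUCES")
        g.add_edge(d1, s2, "TREATS")
        assert len(find_paths(g, LabelPath(["Drug", "INDUCES", "Disease"]))) == 2

    def test_direction_is_respected(self):
        g = PropertyGraph()
        a, b = g.add_node("Drug"), g.add_node("Disease")
        g.add_edge(b, a, "INDUCES")  # reversed
        assert find_paths(g, LabelPath(["Drug", "INDUCES", "Disease"])) == []

    def test_simple_paths_do_not_revisit_nodes(self):
        g = PropertyGraph()
        a, b = g.add_node("X"), g.add_node("X")
        g.add_edge(a, b, "R")
        g.add_edge(b, a, "R")
        paths = find_paths(g, LabelPath(["X", "R", "X", "R", "X"]))
        assert paths == []

    def test_unknown_labels_empty_not_error(self):
        g = PropertyGraph()
        assert find_paths(g, LabelPath(["Nope", "R", "Nada"])) == []

    def test_path_length_guard(self):
        g = PropertyGraph()
        labels = ["A"] + ["R", "A"] * 5  # 11 labels > default max of 10
        with pytest.raises(ValidationError):
            find_paths(g, LabelPath(labels))

    def test_provenance_filter_excludes_other_sources(self):
        a, b = PropertyGraph(), PropertyGraph()
        for g in (a, b):
            d, s = g.add_node("Drug", {"id": "d"}), g.add_node("Disease", {"id": "s"})
            g.add_edge(d, s, "INDUCES")
        merged = merge({"A": a, "B": b})
        paths = find_paths(merged, LabelPath(["Drug", "INDUCES", "Disease"]), source_id="A")
        assert len(paths) == 1
        assert all(merged.node(n.node_id).properties[PROVENANCE_KEY] == "A"
                   for n in paths[0].nodes)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        g = build_random_graph(rng, max_nodes=25, node_labels=("A", "B"),
                               edge_labels=("R", "S"), density=2.5, with_properties=False)
        length = rng.choice([3, 5, 7])
        labels = [rng.choice(["A", "B"]) if i % 2 == 0 else rng.choice(["R", "S"])
                  for i in range(length)]
        got = {
            (tuple(n.node_id for n in p.nodes), tuple(e.edge_id for e in p.edges))
            for p in find_paths(g, LabelPath(labels))
        }
        assert got == path_oracle(g, labels)

    def test_deterministic_order(self, rng):
        g = build_random_graph(rng, max_nodes=25, node_labels=("A", "B"),
                               edge_labels=("R",), density=3.0, with_properties=False)
        labels = LabelPath(["A", "R", "B"])
        first = [(p.nodes[0].node_id, p.edges[0].edge_id) for p in find_paths(g, labels)]
        second = [(p.nodes[0].node_id, p.edges[0].edge_id) for p in find_paths(g, labels)]
        assert first == second


# -- path mapping -----------------------------------------------------------


def _targets_fixture():
    """One source: gene/drug pair joined by TARGETS, both describable."""
    g = PropertyGraph()
    drug = g.add_node("Drug", {"id": "imatinib", "unii": "U1"})
    gene = g.add_node("Gene", {"id": "ABL1", "symbol": "ABL1"})
    g.add_edge(drug, gene, "TARGETS")
    describer = DictDescriber(
        {"Drug": ("Drug", [("UNII", "unii")]), "Gene": ("Gene", [("HGNC_SYMBOL", "symbol")])},
        paths=[["Drug", "TARGETS", "Gene"]],
    )
    return g, describer


class TestMapPaths:
    def test_trivial_edge_mapping(self):
        g, describer = _targets_fixture()
        merged = merge({"A": g})
        build_mapping_layer(merged, {"A": describer})
        edges = mapping_edges(merged)
        assert len(edges) == 1
        assert edges[0].label == "TARGETS"
        assert edges[0].properties[PROVENANCE_KEY] == "A"
        assert merged.node(edges[0].from_id).label == MAPPING_LABEL_PREFIX + "Drug"
        assert merged.node(edges[0].to_id).label == MAPPING_LABEL_PREFIX + "Gene"

    def test_unmapped_terminal_produces_nothing(self):
        g = PropertyGraph()
        drug = g.add_node("Drug", {"id": "d", "unii": "U1"})
        gene = g.add_node("Gene", {"id": "g", "symbol": "G"})
        g.add_edge(drug, gene, "TARGETS")
        merged = merge({"A": g})
        describer = DictDescriber(
            {"Drug": ("Drug", [("UNII", "unii")])},  # genes never described
            paths=[["Drug", "TARGETS", "Gene"]],
        )
        build_mapping_layer(merged, {"A": describer})
        assert mapping_edges(merged) == []

    def test_two_sources_give_parallel_mapping_edges(self):
        graphs, describers = {}, {}
        for sid in ("A", "B"):
            g = PropertyGraph()
            d = g.add_node("Drug", {"id": "d", "unii": "U1"})
            s = g.add_node("Disease", {"id": "s", "mesh": "M1"})
            g.add_edge(d, s, "INDUCES")
            graphs[sid] = g
            describers[sid] = DictDescriber(
                {"Drug": ("Drug", [("UNII", "unii")]),
                 "Disease": ("Disease", [("MESH", "mesh")])},
                paths=[["Drug", "INDUCES", "Disease"]],
            )
        merged = merge(graphs)
        build_mapping_layer(merged, describers)
        assert len(mapping_nodes(merged)) == 2  # one Drug + one Disease (collapsed)
        edges = mapping_edges(merged)
        assert len(edges) == 2
        assert {e.properties[PROVENANCE_KEY] for e in edges} == {"A", "B"}
        assert len({(e.from_id, e.to_id, e.label) for e in edges}) == 1  # truly parallel

    def test_duplicate_paths_same_source_deduplicated(self):
        g = PropertyGraph()
        d = g.add_node("Drug", {"id": "d", "unii": "U1"})
        s = g.add_node("Disease", {"id": "s", "mesh": "M1"})
        g.add_edge(d, s, "INDUCES")
        g.add_edge(d, s, "INDUCES")  # parallel source edges
        merged = merge({"A": g})
        describer = DictDescriber(
            {"Drug": ("Drug", [("UNII", "unii")]), "Disease": ("Disease", [("MESH", "mesh")])},
            paths=[["Drug", "INDUCES", "Disease"]],
        )
        build_mapping_layer(merged, {"A": describer})
        assert len(mapping_edges(merged)) == 1

    def test_two_hop_annotation_path(self):
        g = PropertyGraph()
        variant = g.add_node("Variant", {"id": "rs1", "rsid": "rs1"})
        annotation = g.add_node("VariantDrugAnnotation", {"id": "ann1"})
        chemical = g.add_node("Chemical", {"id": "c1", "unii": "U9"})
        g.add_edge(variant, annotation, "ASSOCIATED_WITH")
        g.add_edge(annotation, chemical, "ASSOCIATED_WITH")
        merged = merge({"A": g})
        describer = DictDescriber(
            {"Variant": ("Variant", [("DBSNP", "rsid")]),
             "Chemical": ("Chemical", [("UNII", "unii")])},
            paths=[["Variant", "ASSOCIATED_WITH", "VariantDrugAnnotation",
                    "ASSOCIATED_WITH", "Chemical"]],
        )
        build_mapping_layer(merged, {"A": describer})
        edges = mapping_edges(merged)
        assert len(edges) == 1
        assert edges[0].label == "ASSOCIATED_WITH"
        assert merged.node(edges[0].from_id).label == MAPPING_LABEL_PREFIX + "Variant"
        assert merged.node(edges[0].to_id).label == MAPPING_LABEL_PREFIX + "Chemical"


# -- run_mapping ------------------------------------------------------------


class TestRunMapping:
    def _fixture_workspace(self, tmp_path):
        ws = create_workspace(tmp_path / "w")
        modules = builtin_fixtures()
        ws.config.data_source_ids = [m.id for m in modules]
        ws.save_config()
        registry = DataSourceRegistry()
        for m in modules:
            registry.register(m)
        return ws, registry, modules

    def test_missing_merged_graph_is_explicit_error(self, tmp_path):
        ws, registry, _ = self._fixture_workspace(tmp_path)
        with pytest.raises(MergedGraphMissingError, match="merge"):
            run_mapping(ws, registry)

    def test_merged_file_unchanged_and_submerged_in_mapped(self, tmp_path):
        from graphdwh import run_source_pipeline

        ws, registry, modules = self._fixture_workspace(tmp_path)
        graphs = []
        for module in modules:
            run_source_pipeline(module, ws)
            graphs.append((module.id, read_graphml(ws.intermediate_graph_path(module.id))))
        write_merged(ws, merge(graphs))
        checksum = ws.merged_graph_path.read_bytes()
        mapped_path = run_mapping(ws, registry)
        assert ws.merged_graph_path.read_bytes() == checksum
        merged = read_graphml(ws.merged_graph_path)
        mapped = read_graphml(mapped_path)
        mapped_nodes = list(mapped.nodes())
        for original, copy in zip(merged.nodes(), mapped_nodes):
            assert (original.label, original.properties) == (copy.label, copy.properties)
        # repeat run is a byte-identical fixed point
        first = mapped_path.read_bytes()
        assert run_mapping(ws, registry).read_bytes() == first

    def test_vacuous_mapping_adds_nothing(self, tmp_path, rng):
        ws = create_workspace(tmp_path / "w")
        ws.config.data_source_ids = ["A"]
        ws.save_config()
        merged = merge({"A": build_random_graph(rng, max_nodes=10)})
        write_merged(ws, merged)
        registry = DataSourceRegistry()  # "A" unresolvable: zero describers
        mapped = read_graphml(run_mapping(ws, registry))
        assert mapped.node_count == merged.node_count
        assert mapped.edge_count == merged.edge_count
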