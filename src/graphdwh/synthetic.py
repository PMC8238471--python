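"""Fixture data sources and a parameterized workspace generator.

Real biomedical sources (gene nomenclatures, drug vocabularies, drug–disease
relation databases) need network downloads; the fixtures here emulate their
*shapes* — heterogeneous raw formats (TSV tables, JSON records, multi-file
sources), cross-source identifier overlap, and relationship motifs that
exercise both trivial edge mapping and two-edge annotation-path mapping —
with fully synthetic tokens. Identifiers and names are fabricated; no
statistical realism of biological content is attempted.

Two kinds of fixtures are provided:

* :func:`builtin_fixtures` — three hand-written modules (a gene table, a
  drug vocabulary with target/induces relations, a relation source with an
  annotation-node motif) whose mapping outcome is known exactly.
* :func:`generate_fixture_workspace` — a generator driven by an
  :class:`OverlapSpec` that fabricates raw files with controlled identifier
  overlap and returns a constructively computed :class:`GroundTruth`
  (which entities must co-map, which mapping edges must exist), independent
  of the mapping algorithm itself.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .datasource import (
    DataSourceModule,
    DataSourceRegistry,
    GlobalIdentifier,
    LabelPath,
    MappingDescriber,
    NodeMappingDescription,
    PathMappingDescription,
)
from .errors import ValidationError
from .mapper import mapping_edges, mapping_membership, mapping_nodes
from .merger import PROVENANCE_KEY
from .property_graph import PropertyGraph
from .workspace import Workspace, create_workspace


# -- generic in-memory-file module ----------------------------------------


class InMemoryFileSource(DataSourceModule):
    """A data source whose raw files live in memory; ``update`` writes them.

    Stands in for a network updater: the "newest version" is the fixture's
    own version string, and updating simply materializes the files into the
    workspace's raw folder.
    """

    def __init__(self, source_id: str, version: str, files: dict[str, str],
                 describer: MappingDescriber):
        self.id = source_id
        self._version = version
        self._files = dict(files)
        self._describer = describer

    def get_newest_version(self) -> str:
        return self._version

    def update(self, raw_dir: Path) -> list[str]:
        for name, content in self._files.items():
            (raw_dir / name).write_text(content, encoding="utf-8")
        return list(self._files)

    @property
    def mapping_describer(self) -> MappingDescriber:
        return self._describer


def _read_tsv(path: Path) -> list[dict]:
    with path.open(encoding="utf-8", newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))


# -- builtin fixture 1: gene nomenclature table ----------------------------

_GENES_TSV = """symbol\thgnc_id\tname
BRCA2\tHGNC:1101\tBRCA2 DNA repair associated
TP53\tHGNC:11998\ttumor protein p53
EGFR\tHGNC:3236\tepidermal growth factor receptor
KCNH2\tHGNC:6251\tpotassium voltage-gated channel subfamily H member 2
"""


class _GeneDescriber(MappingDescriber):
    describable_node_labels = frozenset({"Gene"})
    describable_paths: Sequence[LabelPath] = ()

    def describe_node(self, node):
        return NodeMappingDescription(
            "Gene",
            {
                GlobalIdentifier("HGNC_SYMBOL", node["symbol"]),
                GlobalIdentifier("HGNC_ID", node["hgnc_id"]),
            },
        )


class GeneTableSource(InMemoryFileSource):
    """Gene-nomenclature fixture: one TSV of symbols and accession ids."""

    def __init__(self):
        super().__init__("ToyGenes", "2024.1", {"genes.tsv": _GENES_TSV}, _GeneDescriber())

    def parse(self, raw_dir: Path) -> list[dict]:
        return _read_tsv(raw_dir / "genes.tsv")

    def export_graph(self, records) -> PropertyGraph:
        graph = PropertyGraph()
        for row in records:
            graph.add_node("Gene", {
                "id": row["symbol"], "symbol": row["symbol"],
                "hgnc_id": row["hgnc_id"], "name": row["name"],
            })
        return graph


# -- builtin fixture 2: drug vocabulary with targets/induces ---------------

_DRUGS_JSON = json.dumps(
    [
        {"name": "Imatinib", "unii": "BKJ8M8G5HI", "rxnorm_cui": "282388",
         "targets": ["EGFR"], "induces": []},
        {"name": "Tamoxifen", "unii": "094ZI81Y45", "rxnorm_cui": "10324",
         "targets": ["BRCA2", "TP53"], "induces": ["MESH:D006528"]},
        {"name": "Dofetilide", "unii": "R4Z9X1N2ND",
         "targets": ["KCNH2"], "induces": ["MESH:D001145"]},
    ],
    indent=2,
)


class _DrugDescriber(MappingDescriber):
    describable_node_labels = frozenset({"Drug", "Gene", "Disease"})
    describable_paths = (
        LabelPath(["Drug", "TARGETS", "Gene"]),
        LabelPath(["Drug", "INDUCES", "Disease"]),
    )

    def describe_node(self, node):
        if node.label == "Drug":
            identifiers = {GlobalIdentifier("UNII", node["unii"])}
            if "rxnorm_cui" in node.properties:
                identifiers.add(GlobalIdentifier("RXNORM_CUI", node["rxnorm_cui"]))
            return NodeMappingDescription("Drug", identifiers)
        if node.label == "Gene":
            return NodeMappingDescription(
                "Gene", {GlobalIdentifier("HGNC_SYMBOL", node["symbol"])}
            )
        return NodeMappingDescription("Disease", {GlobalIdentifier("MESH", node["id"])})

    def describe_path(self, path):
        return PathMappingDescription(path.edges[0].label)


class DrugVocabularySource(InMemoryFileSource):
    """Drug-vocabulary fixture: JSON records with ingredient and clinical
    identifiers plus gene targets and induced diseases."""

    def __init__(self):
        super().__init__("ToyDrugs", "7.4", {"drugs.json": _DRUGS_JSON}, _DrugDescriber())

    def parse(self, raw_dir: Path) -> list[dict]:
        return json.loads((raw_dir / "drugs.json").read_text(encoding="utf-8"))

    def export_graph(self, records) -> PropertyGraph:
        graph = PropertyGraph()
        genes: dict[str, int] = {}
        diseases: dict[str, int] = {}
        for record in records:
            props = {"id": record["unii"], "unii": record["unii"], "name": record["name"]}
            if "rxnorm_cui" in record:
                props["rxnorm_cui"] = record["rxnorm_cui"]
            drug = graph.add_node("Drug", props)
            for symbol in record["targets"]:
                if symbol not in genes:
                    genes[symbol] = graph.add_node(
                        "Gene", {"id": symbol, "symbol": symbol}
                    ).node_id
                graph.add_edge(drug.node_id, genes[symbol], "TARGETS")
            for mesh in record["induces"]:
                if mesh not in diseases:
                    diseases[mesh] = graph.add_node("Disease", {"id": mesh}).node_id
                graph.add_edge(drug.node_id, diseases[mesh], "INDUCES")
        return graph


# -- builtin fixture 3: relation source with annotation motif --------------

_RELATIONS_TSV = """drug_unii\tdrug_name\tdisease_id\trelation
094ZI81Y45\tTamoxifen\tMESH:D006528\tINDUCES
R4Z9X1N2ND\tDofetilide\tMESH:D001145\tINDUCES
BKJ8M8G5HI\tImatinib\tMESH:D005767\tINDUCES
"""

_ANNOTATIONS_TSV = """annotation_id\tvariant_rsid\tchemical_unii
VDA001\trs121913529\tBKJ8M8G5HI
VDA002\trs28897696\t094ZI81Y45
"""


class _RelationDescriber(MappingDescriber):
    describable_node_labels = frozenset({"Drug", "Disease", "Variant", "Chemical"})
    describable_paths = (
        LabelPath(["Drug", "INDUCES", "Disease"]),
        LabelPath(["Variant", "ASSOCIATED_WITH", "VariantDrugAnnotation",
                   "ASSOCIATED_WITH", "Chemical"]),
    )

    def describe_node(self, node):
        if node.label == "Drug":
            return NodeMappingDescription("Drug", {GlobalIdentifier("UNII", node["unii"])})
        if node.label == "Disease":
            return NodeMappingDescription("Disease", {GlobalIdentifier("MESH", node["id"])})
        if node.label == "Variant":
            return NodeMappingDescription("Variant", {GlobalIdentifier("DBSNP", node["rsid"])})
        return NodeMappingDescription("Chemical", {GlobalIdentifier("UNII", node["unii"])})

    def describe_path(self, path):
        if len(path.edges) == 1:
            return PathMappingDescription("INDUCES")
        return PathMappingDescription("ASSOCIATED_WITH")


class RelationSource(InMemoryFileSource):
    """Multi-file relation fixture: drug–disease relations plus a
    variant–annotation–chemical motif (two-edge path mapping)."""

    def __init__(self):
        super().__init__(
            "ToyRelations", "2023-10",
            {"relations.tsv": _RELATIONS_TSV, "annotations.tsv": _ANNOTATIONS_TSV},
            _RelationDescriber(),
        )

    def parse(self, raw_dir: Path) -> dict:
        return {
            "relations": _read_tsv(raw_dir / "relations.tsv"),
            "annotations": _read_tsv(raw_dir / "annotations.tsv"),
        }

    def export_graph(self, records) -> PropertyGraph:
        graph = PropertyGraph()
        drugs: dict[str, int] = {}
        diseases: dict[str, int] = {}
        for row in records["relations"]:
            if row["drug_unii"] not in drugs:
                drugs[row["drug_unii"]] = graph.add_node("Drug", {
                    "id": row["drug_unii"], "unii": row["drug_unii"],
                    "name": row["drug_name"],
                }).node_id
            if row["disease_id"] not in diseases:
                diseases[row["disease_id"]] = graph.add_node(
                    "Disease", {"id": row["disease_id"]}
                ).node_id
            graph.add_edge(drugs[row["drug_unii"]], diseases[row["disease_id"]], row["relation"])
        for row in records["annotations"]:
            variant = graph.add_node("Variant", {"id": row["variant_rsid"], "rsid": row["variant_rsid"]})
            annotation = graph.add_node("VariantDrugAnnotation", {"id": row["annotation_id"]})
            chemical = graph.add_node("Chemical", {"id": row["chemical_unii"], "unii": row["chemical_unii"]})
            graph.add_edge(variant, annotation, "ASSOCIATED_WITH")
            graph.add_edge(annotation, chemical, "ASSOCIATED_WITH")
        return graph


def builtin_fixtures() -> list[DataSourceModule]:
    """The bundled fixture modules (fresh instances)."""
    return [GeneTableSource(), DrugVocabularySource(), RelationSource()]


# -- parameterized generator -----------------------------------------------


@dataclass(frozen=True)
class OverlapSpec:
    """Parameters of a generated fixture workspace.

    Defaults describe a small but non-trivial warehouse: three sources, 20
    drugs and 20 diseases each, half of each source's entities shared across
    all sources, 1.5 relations per entity of which 30% run through an
    annotation node (exercising two-edge path mapping).
    """

    n_sources: int = 3
    entities_per_source: int = 20
    overlap_fraction: float = 0.5
    relationship_density: float = 1.5
    annotation_path_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_sources < 1 or self.entities_per_source < 1:
            raise ValidationError("n_sources and entities_per_source must be positive")
        for name in ("overlap_fraction", "annotation_path_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.relationship_density < 0:
            raise ValidationError("relationship_density must be non-negative")


GroupKey = frozenset  # frozenset of (source_id, entity uid) member tuples


@dataclass
class GroundTruth:
    """Expected mapping outcome, computed constructively at generation time.

    ``partition`` contains one frozenset of (source_id, entity uid) members
    per expected mapping node; ``mapping_edges`` one (from-group, label,
    to-group, source_id) tuple per expected mapping edge.
    """

    partition: set = field(default_factory=set)
    mapping_edges: set = field(default_factory=set)


@dataclass
class _Entity:
    uid: str
    name: str
    secondary: Optional[str]  # secondary identifier value, if any


class _GeneratedDescriber(MappingDescriber):
    describable_node_labels = frozenset({"Drug", "Disease"})
    describable_paths = (
        LabelPath(["Drug", "INDUCES", "Disease"]),
        LabelPath(["Drug", "ASSOCIATED_WITH", "DrugDiseaseAnnotation",
                   "ASSOCIATED_WITH", "Disease"]),
    )

    def describe_node(self, node):
        if node.label == "Drug":
            identifiers = {GlobalIdentifier("UNII", node["id"])}
            if "rxnorm_cui" in node.properties:
                identifiers.add(GlobalIdentifier("RXNORM_CUI", node["rxnorm_cui"]))
            return NodeMappingDescription("Drug", identifiers)
        return NodeMappingDescription("Disease", {GlobalIdentifier("MESH", node["id"])})

    def describe_path(self, path):
        if len(path.edges) == 1:
            return PathMappingDescription("INDUCES")
        return PathMappingDescription("ASSOCIATED_WITH")


class GeneratedTableSource(InMemoryFileSource):
    """Generated source in multi-file TSV form."""

    def parse(self, raw_dir: Path) -> dict:
        return {
            "drugs": _read_tsv(raw_dir / "drugs.tsv"),
            "diseases": _read_tsv(raw_dir / "diseases.tsv"),
            "relations": _read_tsv(raw_dir / "relations.tsv"),
        }

    def export_graph(self, records) -> PropertyGraph:
        return _export_generated(records)


class GeneratedJsonSource(InMemoryFileSource):
    """Generated source in single-JSON form."""

    def parse(self, raw_dir: Path) -> dict:
        return json.loads((raw_dir / "data.json").read_text(encoding="utf-8"))

    def export_graph(self, records) -> PropertyGraph:
        return _export_generated(records)


def _export_generated(records: dict) -> PropertyGraph:
    graph = PropertyGraph()
    drugs: dict[str, int] = {}
    diseases: dict[str, int] = {}
    for row in records["drugs"]:
        props = {"id": row["uid"], "name": row["name"]}
        if row.get("rxnorm_cui"):
            props["rxnorm_cui"] = row["rxnorm_cui"]
        drugs[row["uid"]] = graph.add_node("Drug", props).node_id
    for row in records["diseases"]:
        diseases[row["uid"]] = graph.add_node(
            "Disease", {"id": row["uid"], "name": row["name"]}
        ).node_id
    for index, row in enumerate(records["relations"]):
        annotated = str(row["annotated"]).lower() in ("1", "true")
        if annotated:
            annotation = graph.add_node("DrugDiseaseAnnotation", {"id": f"ANN{index:04d}"})
            graph.add_edge(drugs[row["drug"]], annotation, "ASSOCIATED_WITH")
            graph.add_edge(annotation, diseases[row["disease"]], "ASSOCIATED_WITH")
        else:
            graph.add_edge(drugs[row["drug"]], diseases[row["disease"]], "INDUCES")
    return graph


def _tsv(rows: list[dict], columns: list[str]) -> str:
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    return "\n".join(lines) + "\n"


@dataclass
class FixtureWorkspaceResult:
    workspace: Workspace
    registry: DataSourceRegistry
    ground_truth: GroundTruth


def generate_fixture_workspace(spec: OverlapSpec, path) -> FixtureWorkspaceResult:
    """Create a workspace whose sources realize ``spec``; raw files are
    deterministic in (spec, seed).

    The ground truth is derived from the construction itself (which world
    entities were handed to which sources), never by running the mapper.
    """
    rng = random.Random(spec.seed)
    n_shared = round(spec.overlap_fraction * spec.entities_per_source)
    n_unique = spec.entities_per_source - n_shared
    total = n_shared + spec.n_sources * n_unique

    def make_world(kind: str, prefix: str, count: int) -> list[_Entity]:
        world = []
        for i in range(count):
            secondary = None
            if kind == "drug" and rng.random() < 0.5:
                secondary = f"RX{i:05d}"
            world.append(_Entity(f"{prefix}{i:05d}", f"{kind}-{i}", secondary))
        return world

    drug_world = make_world("drug", "UNII-D", total)
    disease_world = make_world("disease", "MESH:D", total)

    source_ids = [f"S{i + 1}" for i in range(spec.n_sources)]
    per_source_drugs: dict[str, list[_Entity]] = {}
    per_source_diseases: dict[str, list[_Entity]] = {}
    for index, source_id in enumerate(source_ids):
        lo = n_shared + index * n_unique
        per_source_drugs[source_id] = drug_world[:n_shared] + drug_world[lo:lo + n_unique]
        per_source_diseases[source_id] = disease_world[:n_shared] + disease_world[lo:lo + n_unique]

    # relations: (drug uid, disease uid, annotated) triples per source
    n_relations = round(spec.relationship_density * spec.entities_per_source)
    per_source_relations: dict[str, list[tuple[str, str, bool]]] = {}
    for source_id in source_ids:
        relations = []
        for _ in range(n_relations):
            drug = rng.choice(per_source_drugs[source_id])
            disease = rng.choice(per_source_diseases[source_id])
            relations.append((drug.uid, disease.uid, rng.random() < spec.annotation_path_fraction))
        per_source_relations[source_id] = relations

    # --- constructive ground truth ---------------------------------------
    truth = GroundTruth()
    drug_groups: dict[str, GroupKey] = {}
    disease_groups: dict[str, GroupKey] = {}
    for world, per_source, groups in (
        (drug_world, per_source_drugs, drug_groups),
        (disease_world, per_source_diseases, disease_groups),
    ):
        usage: dict[str, list[str]] = {}
        for source_id in source_ids:
            for entity in per_source[source_id]:
                usage.setdefault(entity.uid, []).append(source_id)
        for uid, users in usage.items():
            group = frozenset((sid, uid) for sid in users)
            groups[uid] = group
            truth.partition.add(group)
    for source_id in source_ids:
        for drug_uid, disease_uid, annotated in per_source_relations[source_id]:
            label = "ASSOCIATED_WITH" if annotated else "INDUCES"
            truth.mapping_edges.add(
                (drug_groups[drug_uid], label, disease_groups[disease_uid], source_id)
            )

    # --- raw files and modules -------------------------------------------
    registry = DataSourceRegistry()
    for index, source_id in enumerate(source_ids):
        drug_rows = [
            {"uid": e.uid, "name": e.name, "rxnorm_cui": e.secondary or ""}
            for e in per_source_drugs[source_id]
        ]
        disease_rows = [
            {"uid": e.uid, "name": e.name} for e in per_source_diseases[source_id]
        ]
        relation_rows = [
            {"drug": d, "disease": s, "annotated": annotated}
            for d, s, annotated in per_source_relations[source_id]
        ]
        describer = _GeneratedDescriber()
        if index % 2 == 0:
            files = {
                "drugs.tsv": _tsv(drug_rows, ["uid", "name", "rxnorm_cui"]),
                "diseases.tsv": _tsv(disease_rows, ["uid", "name"]),
                "relations.tsv": _tsv(relation_rows, ["drug", "disease", "annotated"]),
            }
            module: InMemoryFileSource = GeneratedTableSource(source_id, "1.0", files, describer)
        else:
            payload = {"drugs": drug_rows, "diseases": disease_rows, "relations": relation_rows}
            files = {"data.json": json.dumps(payload, indent=2)}
            module = GeneratedJsonSource(source_id, "1.0", files, describer)
        registry.register(module)

    workspace = create_workspace(path)
    workspace.config.data_source_ids = list(source_ids)
    workspace.save_config()
    return FixtureWorkspaceResult(workspace, registry, truth)


# -- extraction helpers (pipeline output → ground-truth form) --------------


def mapping_partition(graph: PropertyGraph) -> set:
    """Recover the mapping partition from a mapped graph as frozensets of
    (source id, entity ``id`` property) members — the ground-truth form."""
    members: dict[int, set] = {}
    for node_id, mapping_id in mapping_membership(graph).items():
        node = graph.node(node_id)
        members.setdefault(mapping_id, set()).add((node.get(PROVENANCE_KEY), node.get("id")))
    return {frozenset(v) for v in members.values()}


def mapping_edge_keys(graph: PropertyGraph) -> set:
    """Recover mapping edges as (from-group, label, to-group, source id)."""
    members: dict[int, set] = {}
    for node_id, mapping_id in mapping_membership(graph).items():
        node = graph.node(node_id)
        members.setdefault(mapping_id, set()).add((node.get(PROVENANCE_KEY), node.get("id")))
    keys = set()
    for edge in mapping_edges(graph):
        keys.add((
            frozenset(members.get(edge.from_id, ())),
            edge.label,
            frozenset(members.get(edge.to_id, ())),
            edge.get(PROVENANCE_KEY),
        ))
    return keys
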