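"""Data-source module contract, registry and per-source pipeline.

Every data source is a pluggable module implementing four concerns:

* a **version probe** reporting the newest available source version,
* an **updater** placing raw files into the workspace's per-source folder,
* a **parser** turning raw files into in-memory records,
* an **exporter** turning records into a :class:`~graphdwh.property_graph.PropertyGraph`,

plus a :class:`MappingDescriber` that tells the mapper which node labels and
which label paths of this source can be lifted into the mapping meta-layer.
The mapper itself knows nothing about individual sources.
"""

from __future__ import annotations

import logging
import traceback
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

from . import meta_graph
from .errors import (
    DuplicateModuleError,
    ReservedPropertyError,
    UnknownModuleError,
    ValidationError,
)
from .property_graph import Node, PropertyGraph, write_graphml
from .workspace import DataSourceMetadata, Workspace, _now_iso

log = logging.getLogger(__name__)

ENTRY_POINT_GROUP = "graphdwh.datasources"

#: Canonical entity-type vocabulary for mapping nodes. Extensible: a describer
#: may return any label; these are the ones shipped with the core.
CANONICAL_NODE_LABELS = frozenset(
    {"Drug", "Gene", "Protein", "Disease", "Variant", "Chemical", "Pathway", "Species"}
)

#: Global relationship vocabulary for mapping edges; likewise extensible.
GLOBAL_RELATIONSHIP_LABELS = frozenset(
    {"INDICATES", "CONTRAINDICATES", "INDUCES", "TARGETS", "ASSOCIATED_WITH"}
)


@dataclass(frozen=True, order=True)
class GlobalIdentifier:
    """A namespaced identifier, e.g. ``("HGNC_SYMBOL", "BRCA2")``.

    Equality is exact on the (id_type, value) pair after whitespace trimming;
    no fuzzy matching is ever applied.
    """

    id_type: str
    value: str

    def __post_init__(self):
        object.__setattr__(self, "id_type", self.id_type.strip())
        object.__setattr__(self, "value", self.value.strip())
        if not self.id_type or not self.value:
            raise ValidationError(f"identifier parts must be non-empty, got {self!r}")

    def __str__(self) -> str:
        return f"{self.id_type}:{self.value}"


@dataclass(frozen=True)
class LabelPath:
    """Alternating node/edge label pattern: node, edge, node, ..., node.

    Length 3 describes a single edge (``["Drug", "INDUCES", "Disease"]``),
    length 5 a two-edge path through a helper/annotation node, and so on.
    """

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.labels) < 3 or len(self.labels) % 2 == 0:
            raise ValidationError(
                f"label path must have odd length >= 3, got {list(self.labels)}"
            )
        if any(not isinstance(l, str) or not l for l in self.labels):
            raise ValidationError(f"label path entries must be non-empty strings: {list(self.labels)}")

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.labels[0::2]

    @property
    def edge_labels(self) -> tuple[str, ...]:
        return self.labels[1::2]

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class NodeMappingDescription:
    """How a source node appears in the mapping layer: a canonical entity
    label plus the identifiers under which it is known."""

    mapped_label: str
    identifiers: frozenset[GlobalIdentifier]

    def __init__(self, mapped_label: str, identifiers: Iterable[GlobalIdentifier]):
        object.__setattr__(self, "mapped_label", mapped_label)
        object.__setattr__(self, "identifiers", frozenset(identifiers))
        if not self.mapped_label:
            raise ValidationError("mapped_label must be non-empty")
        if not self.identifiers:
            raise ValidationError("a node mapping description needs at least one identifier")


@dataclass(frozen=True)
class PathMappingDescription:
    """The relationship label a matched path contributes to the mapping layer."""

    mapped_relationship_label: str

    def __post_init__(self):
        if not self.mapped_relationship_label:
            raise ValidationError("mapped_relationship_label must be non-empty")


class MappingDescriber(ABC):
    """Per-source description of what can be mapped.

    ``describe_node`` must only describe nodes whose label is declared in
    ``describable_node_labels``; ``describe_path`` only paths matching a
    declared :class:`LabelPath`. Node labels are the source's own (without
    the merged-graph source prefix).
    """

    @property
    @abstractmethod
    def describable_node_labels(self) -> frozenset[str]: ...

    @property
    @abstractmethod
    def describable_paths(self) -> Sequence[LabelPath]: ...

    @abstractmethod
    def describe_node(self, node: Node) -> Optional[NodeMappingDescription]: ...

    def describe_path(self, path) -> Optional[PathMappingDescription]:
        return None


class DataSourceModule(ABC):
    """Base class for data-source implementations."""

    #: unique data-source id, e.g. "HGNC"-like fixture names
    id: str

    @abstractmethod
    def get_newest_version(self) -> str:
        """Newest available source version (opaque string)."""

    @abstractmethod
    def update(self, raw_dir: Path) -> list[str]:
        """Fetch/refresh raw files into ``raw_dir``; returns bare file names."""

    @abstractmethod
    def parse(self, raw_dir: Path) -> Any:
        """Load raw files into in-memory records for the exporter."""

    @abstractmethod
    def export_graph(self, records: Any) -> PropertyGraph:
        """Transform parsed records into the per-source property graph."""

    @property
    @abstractmethod
    def mapping_describer(self) -> MappingDescriber: ...


class DataSourceRegistry:
    """Resolves configured data-source ids to module implementations."""

    def __init__(self) -> None:
        self._modules: dict[str, DataSourceModule] = {}

    def register(self, module: DataSourceModule) -> None:
        if module.id in self._modules:
            raise DuplicateModuleError(f"data source id {module.id!r} is already registered")
        self._modules[module.id] = module

    def resolve(self, data_source_id: str) -> DataSourceModule:
        try:
            return self._modules[data_source_id]
        except KeyError:
            raise UnknownModuleError(
                f"no data source module registered for id {data_source_id!r}"
            ) from None

    def __contains__(self, data_source_id: str) -> bool:
        return data_source_id in self._modules

    def ids(self) -> list[str]:
        return list(self._modules)

    @classmethod
    def with_builtins(cls) -> "DataSourceRegistry":
        """Registry preloaded with the bundled fixture modules and any
        modules advertised through the ``graphdwh.datasources`` entry point."""
        from .synthetic import builtin_fixtures

        registry = cls()
        for module in builtin_fixtures():
            registry.register(module)
        _load_entry_points(registry)
        return registry


def _load_entry_points(registry: DataSourceRegistry) -> None:
    """Plug-in discovery: external packages expose a zero-argument factory
    returning a DataSourceModule under the ``graphdwh.datasources`` group."""
    try:
        from importlib.metadata import entry_points
    except ImportError:  # pragma: no cover
        return
    for entry in entry_points(group=ENTRY_POINT_GROUP):
        try:
            module = entry.load()()
            registry.register(module)
        except Exception as exc:  # external plug-ins must not break the core
            log.warning("could not load data source plug-in %s: %s", entry.name, exc)


# -- per-source pipeline ---------------------------------------------------


def _check_reserved_keys(graph: PropertyGraph) -> None:
    """Modules may not write ``__``-prefixed keys; those are reserved for the
    merger (provenance, stable ids) and the mapper (meta-layer markers)."""
    for node in graph.nodes():
        for key in node.properties:
            if key.startswith("__"):
                raise ReservedPropertyError(
                    f"node property key {key!r} is reserved (label {node.label!r})"
                )
    for edge in graph.edges():
        for key in edge.properties:
            if key.startswith("__"):
                raise ReservedPropertyError(f"edge property key {key!r} is reserved")


def run_source_pipeline(
    module: DataSourceModule, workspace: Workspace, force: bool = False
) -> DataSourceMetadata:
    """Execute update → parse → export for one source.

    The update step is skipped when the stored version already equals the
    newest probed version and a successful export exists (unless ``force``).
    A failing step clears all downstream flags and records the error; the
    metadata file always reflects the outcome.
    """
    workspace.ensure_source_layout(module.id)
    raw_dir = workspace.raw_dir(module.id)
    metadata = workspace.load_metadata(module.id) or DataSourceMetadata()

    try:
        newest = module.get_newest_version()
    except Exception:
        newest = None  # degrade: unknown version, do not update

    up_to_date = (
        newest is not None
        and metadata.version == newest
        and metadata.export_successful
    )
    if up_to_date and not force:
        return metadata  # nothing to do; export re-used

    # update ---------------------------------------------------------------
    if newest is None and metadata.update_successful and not force:
        pass  # probe unreachable but raw files from an earlier update exist
    else:
        try:
            file_names = module.update(raw_dir)
            metadata.version = newest
            metadata.source_file_names = list(file_names)
            metadata.update_date_time = _now_iso()
            metadata.update_successful = True
            metadata.error = None
        except Exception as exc:
            metadata.update_successful = False
            metadata.error = f"update failed: {exc}"
            log.error("update of %s failed:\n%s", module.id, traceback.format_exc())
            metadata.normalize()
            workspace.save_metadata(module.id, metadata)
            return metadata

    # parse ----------------------------------------------------------------
    try:
        records = module.parse(raw_dir)
        metadata.parse_successful = True
    except Exception as exc:
        metadata.parse_successful = False
        metadata.error = f"parse failed: {exc}"
        log.error("parse of %s failed:\n%s", module.id, traceback.format_exc())
        metadata.normalize()
        workspace.save_metadata(module.id, metadata)
        return metadata

    # export ---------------------------------------------------------------
    try:
        graph = module.export_graph(records)
        _check_reserved_keys(graph)
        write_graphml(graph, workspace.intermediate_graph_path(module.id))
        meta_graph.write_statistics(
            meta_graph.compute_meta_graph(graph), workspace.meta_stats_path(module.id)
        )
        metadata.export_successful = True
        metadata.error = None
    except Exception as exc:
        metadata.export_successful = False
        metadata.error = f"export failed: {exc}"
        log.error("export of %s failed:\n%s", module.id, traceback.format_exc())

    metadata.normalize()
    workspace.save_metadata(module.id, metadata)
    return metadata


def validate_describer(
    module: DataSourceModule, sample_graph: Optional[PropertyGraph] = None
) -> list[str]:
    """Static checks on a module's mapping describer; returns violations."""
    violations: list[str] = []
    describer = module.mapping_describer
    for path in describer.describable_paths:
        labels = path.labels if isinstance(path, LabelPath) else tuple(path)
        if len(labels) < 3 or len(labels) % 2 == 0:
            violations.append(
                f"{module.id}: declared path {list(labels)} must have odd length >= 3"
            )
        if any(not l for l in labels):
            violations.append(f"{module.id}: declared path {list(labels)} has empty labels")
    if sample_graph is not None:
        exported_labels = set(sample_graph.node_labels())
        for label in sorted(describer.describable_node_labels):
            if label not in exported_labels:
                violations.append(
                    f"{module.id}: describable node label {label!r} is never exported"
                )
            for node in sample_graph.find_nodes(label):
                try:
                    description = describer.describe_node(node)
                except Exception as exc:
                    violations.append(
                        f"{module.id}: describe_node raised on {label!r} node: {exc}"
                    )
                    break
                if description is not None and not description.identifiers:
                    violations.append(
                        f"{module.id}: describe_node returned empty identifiers for {label!r}"
                    )
    return violations
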