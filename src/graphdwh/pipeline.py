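"""Workspace-level orchestration: per-source pipelines → merge → mapping.

This is the programmatic counterpart of the CLI ``update`` command. Source
failures are isolated: the warehouse is still merged and mapped from the
sources that exported successfully, and the result records who failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import mapper, merger
from .datasource import DataSourceRegistry, run_source_pipeline
from .workspace import DataSourceMetadata, Workspace

log = logging.getLogger(__name__)


@dataclass
class UpdateResult:
    metadata: dict[str, DataSourceMetadata] = field(default_factory=dict)
    failed_source_ids: list[str] = field(default_factory=list)
    merged_path: Optional[Path] = None
    mapped_path: Optional[Path] = None

    @property
    def ok(self) -> bool:
        return not self.failed_source_ids


def update_workspace(
    workspace: Workspace,
    registry: DataSourceRegistry,
    force: bool = False,
    skip_mapping: bool = False,
) -> UpdateResult:
    """Run the full program flow for every configured source.

    Per source: update → parse → export (producing an intermediate GraphML
    and meta-graph statistics). Then all successfully exported intermediates
    are merged into the warehouse graph and, unless ``skip_mapping``, the
    mapping meta-layer is added. A failing or unresolvable source is reported
    in ``failed_source_ids`` but never blocks the others.
    """
    result = UpdateResult()
    exported: list[str] = []
    for source_id in workspace.config.data_source_ids:
        if source_id not in registry:
            log.warning("no module registered for configured source %r", source_id)
            result.failed_source_ids.append(source_id)
            continue
        metadata = run_source_pipeline(registry.resolve(source_id), workspace, force=force)
        result.metadata[source_id] = metadata
        if metadata.export_successful:
            exported.append(source_id)
        else:
            result.failed_source_ids.append(source_id)

    graphs = [
        (source_id, mapper.read_graphml(workspace.intermediate_graph_path(source_id)))
        for source_id in exported
    ]
    merged = merger.merge(graphs)
    result.merged_path = merger.write_merged(workspace, merged)
    if not skip_mapping:
        result.mapped_path = mapper.run_mapping(workspace, registry)
    return result
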