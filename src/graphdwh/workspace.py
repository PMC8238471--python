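"""Workspace layout, JSON configuration and per-source metadata.

A workspace is a self-contained project directory::

    <workspace>/
        config.json                 # workspace format version, creation time,
                                    # configured data-source ids + properties
        sources/
            <DataSourceId>/
                metadata.json       # source version, timestamps, step flags
                source/             # raw downloaded/fetched files
                intermediate.graphml
                meta-graph-statistics.txt
            merged.graphml          # warehouse graph (all sources)
            mapped.graphml          # warehouse graph + mapping meta-layer
            merged-meta-graph-statistics.txt
            mapped-meta-graph-statistics.txt

The JSON field names used here are this implementation's dialect. Source
versions are treated as opaque strings: a source is up to date exactly when
its stored version string equals the version its module currently reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .errors import (
    ValidationError,
    WorkspaceExistsError,
    WorkspaceNotFoundError,
    WorkspaceUpgradeRequiredError,
)

WORKSPACE_FORMAT_VERSION = 1
CONFIG_FILE_NAME = "config.json"
SOURCES_DIR_NAME = "sources"
METADATA_FILE_NAME = "metadata.json"
RAW_DIR_NAME = "source"
INTERMEDIATE_GRAPH_FILE = "intermediate.graphml"
META_STATS_FILE = "meta-graph-statistics.txt"
MERGED_GRAPH_FILE = "merged.graphml"
MAPPED_GRAPH_FILE = "mapped.graphml"
MERGED_STATS_FILE = "merged-meta-graph-statistics.txt"
MAPPED_STATS_FILE = "mapped-meta-graph-statistics.txt"


def _now_iso() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class WorkspaceConfig:
    """Contents of ``config.json``; unknown keys survive a load/save cycle."""

    version: int
    creation_date_time: str
    data_source_ids: list[str] = field(default_factory=list)
    data_source_properties: dict[str, dict[str, str]] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not isinstance(self.version, int) or self.version < 1:
            raise ValidationError(f"config field 'version' must be an integer >= 1, got {self.version!r}")
        if len(set(self.data_source_ids)) != len(self.data_source_ids):
            dupes = sorted({i for i in self.data_source_ids if self.data_source_ids.count(i) > 1})
            raise ValidationError(f"config field 'data_source_ids' contains duplicates: {dupes}")
        unknown = set(self.data_source_properties) - set(self.data_source_ids)
        if unknown:
            raise ValidationError(
                "config field 'data_source_properties' references unconfigured "
                f"data sources: {sorted(unknown)}"
            )

    @classmethod
    def from_dict(cls, raw: dict) -> "WorkspaceConfig":
        for mandatory in ("version", "creation_date_time", "data_source_ids"):
            if mandatory not in raw:
                raise ValidationError(f"config is missing mandatory field {mandatory!r}")
        known = {"version", "creation_date_time", "data_source_ids", "data_source_properties"}
        config = cls(
            version=raw["version"],
            creation_date_time=raw["creation_date_time"],
            data_source_ids=list(raw["data_source_ids"]),
            data_source_properties={k: dict(v) for k, v in raw.get("data_source_properties", {}).items()},
            extras={k: v for k, v in raw.items() if k not in known},
        )
        config.validate()
        if config.version > WORKSPACE_FORMAT_VERSION:
            raise WorkspaceUpgradeRequiredError(
                f"workspace format version {config.version} is newer than the "
                f"supported version {WORKSPACE_FORMAT_VERSION}; upgrade required"
            )
        return config

    def to_dict(self) -> dict:
        payload = {
            "version": self.version,
            "creation_date_time": self.creation_date_time,
            "data_source_ids": list(self.data_source_ids),
            "data_source_properties": {k: dict(v) for k, v in self.data_source_properties.items()},
        }
        payload.update(self.extras)
        return payload


@dataclass
class DataSourceMetadata:
    """Contents of a per-source ``metadata.json``.

    The step flags are monotone: export can only succeed after parse, parse
    only after update. :meth:`normalize` enforces the implication chain.
    """

    version: Optional[str] = None
    update_date_time: Optional[str] = None
    source_file_names: list[str] = field(default_factory=list)
    update_successful: bool = False
    parse_successful: bool = False
    export_successful: bool = False
    error: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def normalize(self) -> None:
        """Clear downstream flags that lack their prerequisite."""
        if not self.update_successful:
            self.parse_successful = False
        if not self.parse_successful:
            self.export_successful = False

    @classmethod
    def from_dict(cls, raw: dict) -> "DataSourceMetadata":
        known = {
            "version", "update_date_time", "source_file_names",
            "update_successful", "parse_successful", "export_successful", "error",
        }
        md = cls(
            version=raw.get("version"),
            update_date_time=raw.get("update_date_time"),
            source_file_names=list(raw.get("source_file_names", [])),
            update_successful=bool(raw.get("update_successful", False)),
            parse_successful=bool(raw.get("parse_successful", False)),
            export_successful=bool(raw.get("export_successful", False)),
            error=raw.get("error"),
            extras={k: v for k, v in raw.items() if k not in known},
        )
        md.normalize()
        return md

    def to_dict(self) -> dict:
        payload = {
            "version": self.version,
            "update_date_time": self.update_date_time,
            "source_file_names": list(self.source_file_names),
            "update_successful": self.update_successful,
            "parse_successful": self.parse_successful,
            "export_successful": self.export_successful,
        }
        if self.error is not None:
            payload["error"] = self.error
        payload.update(self.extras)
        return payload


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def _read_json(path: Path) -> dict:
    try:
        return json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed JSON in {path}: {exc}") from exc


class Workspace:
    """Handle on an existing workspace directory."""

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        self.config_path = self.path / CONFIG_FILE_NAME
        if not self.config_path.is_file():
            raise WorkspaceNotFoundError(f"no workspace found at {self.path} (missing {CONFIG_FILE_NAME})")
        self.config = load_config(self.config_path)

    # -- layout -----------------------------------------------------------

    @property
    def sources_dir(self) -> Path:
        return self.path / SOURCES_DIR_NAME

    def source_dir(self, data_source_id: str) -> Path:
        return self.sources_dir / data_source_id

    def raw_dir(self, data_source_id: str) -> Path:
        return self.source_dir(data_source_id) / RAW_DIR_NAME

    def intermediate_graph_path(self, data_source_id: str) -> Path:
        return self.source_dir(data_source_id) / INTERMEDIATE_GRAPH_FILE

    def meta_stats_path(self, data_source_id: str) -> Path:
        return self.source_dir(data_source_id) / META_STATS_FILE

    @property
    def merged_graph_path(self) -> Path:
        return self.sources_dir / MERGED_GRAPH_FILE

    @property
    def mapped_graph_path(self) -> Path:
        return self.sources_dir / MAPPED_GRAPH_FILE

    def ensure_source_layout(self, data_source_id: str) -> Path:
        """Create ``sources/<id>/source/`` (idempotent); returns the source root."""
        if data_source_id not in self.config.data_source_ids:
            raise ValidationError(
                f"data source {data_source_id!r} is not configured in this workspace"
            )
        self.raw_dir(data_source_id).mkdir(parents=True, exist_ok=True)
        return self.source_dir(data_source_id)

    # -- persistence ------------------------------------------------------

    def save_config(self) -> None:
        self.config.validate()
        _write_json(self.config_path, self.config.to_dict())

    def metadata_path(self, data_source_id: str) -> Path:
        return self.source_dir(data_source_id) / METADATA_FILE_NAME

    def load_metadata(self, data_source_id: str) -> Optional[DataSourceMetadata]:
        path = self.metadata_path(data_source_id)
        if not path.is_file():
            return None
        return DataSourceMetadata.from_dict(_read_json(path))

    def save_metadata(self, data_source_id: str, metadata: DataSourceMetadata) -> None:
        metadata.normalize()
        _write_json(self.metadata_path(data_source_id), metadata.to_dict())


def create_workspace(path: Union[str, Path]) -> Workspace:
    """Create a fresh workspace (config file + ``sources/`` folder) at ``path``.

    Refuses to overwrite an existing workspace.
    """
    path = Path(path)
    if (path / CONFIG_FILE_NAME).exists():
        raise WorkspaceExistsError(f"a workspace already exists at {path}")
    path.mkdir(parents=True, exist_ok=True)
    (path / SOURCES_DIR_NAME).mkdir(exist_ok=True)
    config = WorkspaceConfig(
        version=WORKSPACE_FORMAT_VERSION,
        creation_date_time=_now_iso(),
    )
    _write_json(path / CONFIG_FILE_NAME, config.to_dict())
    return Workspace(path)


def load_config(path: Union[str, Path]) -> WorkspaceConfig:
    return WorkspaceConfig.from_dict(_read_json(Path(path)))


def save_config(path: Union[str, Path], config: WorkspaceConfig) -> None:
    config.validate()
    _write_json(Path(path), config.to_dict())


# -- status ----------------------------------------------------------------


@dataclass
class StatusRow:
    data_source_id: str
    resolvable: bool
    local_version: Optional[str]
    newest_version: Optional[str]
    up_to_date: bool
    last_update_time: Optional[str]


@dataclass
class StatusReport:
    workspace_format_version: int
    rows: list[StatusRow]

    def render(self) -> str:
        """Aligned plain-text table, one row per configured source."""
        header = ("Data source", "Up-to-date", "Version", "Newest version", "Last update")
        body = []
        for row in self.rows:
            if not row.resolvable:
                flag = "unresolvable"
            else:
                flag = "yes" if row.up_to_date else "no"
            body.append((
                row.data_source_id,
                flag,
                row.local_version or "-",
                row.newest_version or "unknown",
                row.last_update_time or "never",
            ))
        widths = [max(len(header[i]), *(len(r[i]) for r in body)) if body else len(header[i])
                  for i in range(len(header))]
        lines = [f"Workspace format version: {self.workspace_format_version}"]
        lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)).rstrip())
        lines.append("  ".join("-" * w for w in widths))
        for r in body:
            lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
        return "\n".join(lines)


def status(workspace: Workspace, registry) -> StatusReport:
    """One row per configured source; version probes that fail mark the
    newest version unknown instead of raising."""
    rows = []
    for source_id in workspace.config.data_source_ids:
        metadata = workspace.load_metadata(source_id)
        local = metadata.version if metadata else None
        last_update = metadata.update_date_time if metadata else None
        resolvable = source_id in registry
        newest = None
        if resolvable:
            try:
                newest = registry.resolve(source_id).get_newest_version()
            except Exception:
                newest = None
        up_to_date = local is not None and newest is not None and local == newest
        rows.append(StatusRow(source_id, resolvable, local, newest, up_to_date, last_update))
    return StatusReport(workspace.config.version, rows)
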