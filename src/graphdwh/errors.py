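"""Exception hierarchy for graphdwh.

All package-specific errors derive from :class:`GraphDWHError` so callers can
catch everything the pipeline may raise with a single except clause.
"""


class GraphDWHError(Exception):
    """Base class for all graphdwh errors."""


class ValidationError(GraphDWHError):
    """A value violates a documented invariant (bad label, property type, ...)."""


class ReservedPropertyError(ValidationError):
    """A data-source module tried to write a reserved (``__``-prefixed) property key."""


class GraphMLError(GraphDWHError):
    """A GraphML document could not be parsed or written."""


class WorkspaceError(GraphDWHError):
    """Base class for workspace-layout problems."""


class WorkspaceExistsError(WorkspaceError):
    """A workspace already exists at the requested location."""


class WorkspaceNotFoundError(WorkspaceError):
    """No workspace (config file) found at the requested location."""


class WorkspaceUpgradeRequiredError(WorkspaceError):
    """The on-disk workspace format version is newer than this package supports."""


class RegistryError(GraphDWHError):
    """Base class for data-source registry problems."""


class DuplicateModuleError(RegistryError):
    """A data-source id was registered twice."""


class UnknownModuleError(RegistryError):
    """A configured data-source id has no registered implementation."""


class MergedGraphMissingError(GraphDWHError):
    """Mapping was requested but no merged graph exists; run the merge step first."""
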