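"""Exception hierarchy for the clintypes library."""


class ClintypesError(Exception):
    """Base class for all library errors."""


class SchemaError(ClintypesError):
    """Raised for meta-level problems: duplicate or unknown type names,
    unknown namespaces, unresolvable feature ranges, malformed schema files."""


class StoreError(ClintypesError):
    """Raised when a document store operation fails (validation violations
    on add, dangling references, out-of-range query windows)."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])


class BridgeError(ClintypesError):
    """Raised by the mention-to-element resolution bridge, e.g. for a
    coreference chain mixing entity and event mentions, or a feature
    conflict under the ``error`` conflict policy."""


class CemError(ClintypesError):
    """Raised for cetype XML dialect problems and CEM instance-building
    failures (cardinality violations, model/type mismatches)."""
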