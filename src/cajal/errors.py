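"""Exception hierarchy shared across the package."""


class CajalError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(CajalError):
    """Morphology graph is not a valid tree (cycle, missing or multiple roots)."""


class ParseError(CajalError):
    """Mechanism DSL source could not be tokenized/parsed."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SemanticError(ParseError):
    """Mechanism DSL parsed but violates a semantic rule (undeclared symbol, ...)."""


class SingularSystemError(CajalError):
    """Zero pivot encountered while factorizing a tree system."""


class NumericError(CajalError):
    """Numerical failure during simulation (NaN/overflow, Newton divergence)."""


class ConsistencyError(CajalError):
    """State/archive shape does not match the constructed model."""


class UnsupportedExtensionError(CajalError):
    """State archive references an extension id that is not registered."""


class ConflictError(CajalError):
    """Conflicting registration (duplicate extension id, overlapping species)."""


class ConfigError(CajalError):
    """Run configuration file is invalid."""

    def __init__(self, message, keys=()):
        self.keys = list(keys)
        if self.keys:
            message = f"{message} (offending keys: {', '.join(self.keys)})"
        super().__init__(message)
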