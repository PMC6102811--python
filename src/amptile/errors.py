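"""Exception types raised across the pipeline."""


class AmptileError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(AmptileError, ValueError):
    """An operation received an invalid parameter value."""


class DesignError(AmptileError, ValueError):
    """A requested amplicon/library design is geometrically infeasible."""


class PanelError(AmptileError, ValueError):
    """A primer/barcode panel violates its invariants."""


class AssemblyError(AmptileError, RuntimeError):
    """Overlap layout is contradictory (inconsistent offsets or cycles)."""


class ConfigError(AmptileError, ValueError):
    """A run-parameters file is malformed or inconsistent."""
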