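"""Exception hierarchy shared across the package."""


class NickhdrError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NickhdrError):
    """A locus/guide/template configuration file is malformed."""


class ConsistencyError(NickhdrError):
    """Configured values disagree with the reference sequence."""


class InputError(NickhdrError):
    """Invalid runtime input (bad symbols, overlapping edits, bad counts)."""


class DesignInfeasibleError(NickhdrError):
    """No silent substitution is available where the design requires one."""


class SimulationError(NickhdrError):
    """The requested simulation cannot produce reads (e.g. nothing capturable)."""
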