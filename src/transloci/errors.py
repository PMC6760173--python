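"""Exception hierarchy shared across the package."""


class TransLociError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TransLociError):
    """An input table is missing a mandatory column or has an unusable header."""


class ValidationError(TransLociError):
    """A record violates a domain invariant (e.g. p outside (0, 1])."""


class UnsupportedFormatError(TransLociError):
    """The file is syntactically readable but uses an unsupported encoding
    (e.g. mixed ploidy or multi-allelic sites in a VCF)."""


class TransformError(TransLociError):
    """A phenotype transformation is undefined for the given input."""


class ConfigurationError(TransLociError):
    """A simulation or analysis configuration is internally inconsistent."""


class SimulationError(TransLociError):
    """A simulation cannot proceed (e.g. monomorphic causal variant)."""


class ScenarioError(SimulationError):
    """No causal-variant assignment satisfies the scenario constraints."""
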