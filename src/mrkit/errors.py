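"""Exception hierarchy shared across the package."""


class MRKitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRKitError):
    """Invalid configuration: bad threshold, missing column map entry, missing seed."""


class ValidationError(MRKitError):
    """Input data violates an invariant (bad allele, non-positive SE, duplicate ID...)."""


class InsufficientInstrumentsError(MRKitError):
    """An estimator or diagnostic was called with fewer instruments than it requires."""


class DegenerateInstrumentError(MRKitError):
    """A per-SNP operation hit a degenerate input (e.g. zero exposure effect)."""


class EmptyInstrumentSetError(MRKitError):
    """A selection stage emptied the instrument set; carries the stage name."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"no instruments survive selection stage {stage!r}")
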