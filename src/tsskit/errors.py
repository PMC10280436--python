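"""Exception hierarchy shared across the toolkit."""


class TSSKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(TSSKitError, ValueError):
    """A configuration object or argument violates its invariants."""


class ContractError(TSSKitError, ValueError):
    """Caller violated an operation's precondition (shapes, lengths, types)."""


class BoundaryError(TSSKitError, ValueError):
    """A requested genomic window does not fit inside its chromosome."""


class ChromosomeLookupError(TSSKitError, KeyError):
    """A chromosome name is absent from the assembly."""


class AmbiguousBaseError(TSSKitError, ValueError):
    """A sequence span contains a character outside {A, C, G, T}."""


class EncodingError(TSSKitError, ValueError):
    """A sequence cannot be one-hot encoded."""


class SchemaError(TSSKitError, ValueError):
    """An input table is missing a required column."""


class DatasetParseError(TSSKitError, ValueError):
    """A stored dataset file is malformed."""


class TrainingError(TSSKitError, ValueError):
    """A model cannot be trained on the given data (e.g. single-class input)."""


class MetricError(TSSKitError, ValueError):
    """A metric is undefined for the given labels (e.g. single-class AUC)."""
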