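"""Error taxonomy shared across the package.

The CLI maps these onto exit codes: configuration errors exit 2, data
errors exit 3, anything else exits 4.
"""


class FedHerdError(Exception):
    """Base class for all package errors."""


class ConfigError(FedHerdError):
    """A configuration value is missing, out of range, or inconsistent."""


class PartitionError(ConfigError):
    """A requested client partition is infeasible (e.g. more clients than animals)."""


class DataError(FedHerdError):
    """Input data violates a precondition (missing values, empty table, bad order)."""


class GuardError(DataError):
    """Pipeline-order misuse detected (e.g. labelling already-normalized values)."""


class AggregationError(DataError):
    """Federated aggregation received unusable updates (e.g. zero total samples)."""


class StructuralError(FedHerdError):
    """Array shapes are inconsistent with the model configuration."""
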