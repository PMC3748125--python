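"""Exception hierarchy shared across the package."""


class AggloSegError(Exception):
    """Base class for all package-specific errors."""


class InputError(AggloSegError, ValueError):
    """Invalid input data (shape mismatch, empty volume, out-of-range cues)."""


class MissingEdgeError(AggloSegError, KeyError):
    """An operation referenced an edge that does not exist in the graph."""


class ConsistencyError(AggloSegError, RuntimeError):
    """Internal state disagrees with the data it was derived from."""


class SchemaError(AggloSegError, ValueError):
    """A policy's feature schema does not match the graph it is applied to."""


class DegenerateTrainingError(AggloSegError, ValueError):
    """The training set cannot support fitting (e.g. a single class)."""
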