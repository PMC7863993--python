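"""Exception hierarchy shared across the package."""


class FFBenchError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(FFBenchError):
    """Malformed input file (SDF record, assignment table, config)."""


class GraphError(FFBenchError):
    """Invalid molecular graph (disconnected, bad indices, bad element)."""


class MetricError(FFBenchError):
    """A metric is undefined for the given input (empty torsion set, ...)."""
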