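"""Exception hierarchy shared by all hetpath modules."""


class HetpathError(Exception):
    """Base class for all package-specific errors."""


class IdentifierError(HetpathError, KeyError):
    """An unknown node, node type, or metaedge was referenced."""

    def __str__(self) -> str:  # KeyError quotes its args; keep plain messages
        return Exception.__str__(self)


class SchemaError(HetpathError):
    """Data contradicts the metagraph or a table's declared layout."""


class ReferentialIntegrityError(HetpathError):
    """An edge references a node that does not exist."""


class EmptyNetworkError(HetpathError):
    """An operation would leave the network without nodes or metaedges."""


class BudgetError(HetpathError):
    """An exhaustive computation exceeded its enumeration budget."""


class SamplingError(HetpathError):
    """A random sample was requested from a pool that is too small."""


class MetricUndefinedError(HetpathError):
    """A metric was requested on inputs where it is undefined."""


class ConfigurationError(HetpathError):
    """A configuration object is internally inconsistent or infeasible."""
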