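"""Exception hierarchy for the federated query engine.

Every user-facing failure derives from :class:`FedKGError` so callers (and the
CLI) can distinguish engine diagnostics from programming errors.
"""


class FedKGError(Exception):
    """Base class for all engine errors."""


class HierarchyError(FedKGError):
    """Malformed category/predicate hierarchy (cycle, orphan, unknown token)."""


class SpecValidationError(FedKGError):
    """An API spec document violates the annotation dialect."""


class RegistryError(FedKGError):
    """Registry-level inconsistency (duplicate op ids, missing files)."""


class QueryValidationError(FedKGError):
    """A query graph or response document violates its invariants."""


class CurieError(QueryValidationError):
    """A compact identifier string is not of the form ``prefix:local_id``."""


class PlanningError(FedKGError):
    """No operation in the registry can serve any edge of the query."""


class IdPathError(FedKGError):
    """A ``response_id_path`` expression does not parse."""


class TransportError(FedKGError):
    """An API call failed at the transport level (isolated per operation)."""


class UnknownOperationError(TransportError):
    """The transport was asked to serve an operation it does not know.

    Distinguishable from an empty result and from a simulated outage.
    """


class UndefinedTermError(FedKGError):
    """Normalized Google Distance requested for a term with zero occurrences."""


class GenerationError(FedKGError):
    """Synthetic-network parameters are infeasible."""
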