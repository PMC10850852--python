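"""Exception hierarchy for the patient-similarity toolkit.

Every error carries enough context (term id, indicator name, patient pair)
to locate the offending input; readers and pipeline stages re-raise with
location information rather than silently coercing.
"""


class ChdpsnError(Exception):
    """Base class for all toolkit errors."""


class OntologyStructureError(ChdpsnError):
    """The diagnosis hierarchy violates a structural invariant (cycle,
    multiple roots, no root)."""


class TermNotFoundError(ChdpsnError, KeyError):
    """A diagnosis term id does not resolve in the ontology."""


class SchemaError(ChdpsnError):
    """An indicator is missing from, or inconsistent with, the schema."""


class TransformError(ChdpsnError):
    """A preprocessing transform cannot be fitted or applied."""


class ConfigurationError(ChdpsnError):
    """Invalid weights, criteria, or run configuration."""


class PredictionError(ChdpsnError):
    """A prediction cannot be made (e.g. empty similarity group)."""


class DataAvailabilityError(ChdpsnError):
    """A clinical phase requires a feature group that is absent."""


class LeakageError(ChdpsnError):
    """Train and test cohorts overlap, or an index outcome would be read."""


class EvaluationError(ChdpsnError):
    """An evaluation quantity is undefined on the given inputs."""
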