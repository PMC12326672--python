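"""Exception hierarchy shared across the package."""


class GbaDtiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GbaDtiError, ValueError):
    """Input violates a domain invariant (duplicate ids, bad labels, ...)."""


class FormatError(GbaDtiError, ValueError):
    """A file does not conform to its expected on-disk format."""


class FeaturizationError(GbaDtiError, ValueError):
    """An entity could not be converted to a feature vector.

    Carries the offending entity id in ``entity_id`` when known.
    """

    def __init__(self, message: str, entity_id: str | None = None):
        super().__init__(message)
        self.entity_id = entity_id


class DegenerateEmbeddingError(GbaDtiError, ValueError):
    """An embedding has (near-)zero norm and cannot be cosine-scored.

    Raised rather than silently returning 0 — a zero embedding indicates
    broken training and would corrupt rankings.
    """

    def __init__(self, message: str, entity_ids: list[str] | None = None):
        super().__init__(message)
        self.entity_ids = entity_ids or []


class UndefinedMetricError(GbaDtiError, ValueError):
    """A ranking metric is undefined (e.g. single-class labels)."""
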