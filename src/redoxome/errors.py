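"""Exception hierarchy for the redoxome pipeline.

Every validation failure raises a located, typed error; records violating an
invariant are never silently dropped.
"""


class RedoxomeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(RedoxomeError):
    """Malformed input file (missing column, empty sequence, bad token)."""


class DesignError(RedoxomeError):
    """Plex-design invariant violation (missing fraction, duplicate channel,
    or a quant record referencing a channel absent from the design)."""


class CrossReferenceError(RedoxomeError):
    """A record references a protein accession absent from the sequence db."""


class ConsistencyError(RedoxomeError):
    """A site position does not point at a cysteine in its protein."""


class AnnotationError(RedoxomeError):
    """Domain-annotation invariant violation (overlap, out-of-bounds)."""


class ConfigError(RedoxomeError):
    """Invalid configuration value."""


class InsufficientReplicatesError(RedoxomeError):
    """Fewer than two quantified replicates in a group at test time."""


class EmptyResultError(RedoxomeError):
    """An operation that requires a non-empty input received none."""
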