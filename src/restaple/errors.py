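"""Exception hierarchy for restaple.

Every error raised by the library derives from :class:`RestapleError`, so
callers (and the CLI) can catch one base class. Subclasses map onto the
stages of the pipeline: file dialect problems, strand-linkage problems,
layout infeasibility, sequence assignment, search, and export consistency.
"""


class RestapleError(Exception):
    """Base class for all restaple errors."""


class CadnanoParseError(RestapleError):
    """The input is not syntactically valid JSON."""


class SchemaError(RestapleError):
    """The JSON is valid but is not a caDNAno version-2 design."""


class UnsupportedFeatureError(RestapleError):
    """The design uses a caDNAno feature restaple declines to model.

    Currently: loop (insertion) values > 0, scadnano files and the
    caDNAno 2.5 dialect.
    """


class LinkageError(RestapleError):
    """A scaffold/staple pointer dangles or is not mutually consistent."""


class TopologyError(RestapleError):
    """Strand components do not match what an operation requires
    (e.g. a design with zero or several scaffold strands)."""


class ConsistencyError(RestapleError):
    """Two objects that must describe the same design disagree
    (layout vs design, or exported files failing cross-validation)."""


class FixtureError(RestapleError):
    """A synthetic-design specification is geometrically infeasible."""


class LayoutInfeasibleError(RestapleError):
    """No staple segmentation/grouping satisfying the config was found."""


class SequenceAssignmentError(RestapleError):
    """Predefined sequences cannot be matched to the layout's groups."""


class GenerationError(RestapleError):
    """Random sequence generation could not satisfy its constraints
    (e.g. GC bounds) within the retry budget."""


class SearchError(RestapleError):
    """Every draw of a design search was infeasible."""
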