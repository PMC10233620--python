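"""Exception hierarchy for glycovalid."""


class GlycoValidError(Exception):
    """Base class for all glycovalid errors."""


class ParseError(GlycoValidError):
    """A coordinate or table file could not be parsed."""


class FormatError(GlycoValidError):
    """An unsupported or unrecognised file format was requested."""


class ValidationInputError(GlycoValidError):
    """An input table row violates a documented invariant."""


class IncompleteRingError(GlycoValidError):
    """A pyranose residue is missing one or more ring atoms."""

    def __init__(self, missing, residue=None):
        self.missing = tuple(missing)
        self.residue = residue
        super().__init__(f"incomplete ring, missing atoms: {', '.join(self.missing)}")


class GeometryError(GlycoValidError):
    """Degenerate geometry (coincident/collinear points, planar ring)."""


class UndefinedTorsionError(GeometryError):
    """Collinear atoms make a torsion angle undefined."""


class PlanarRingError(GeometryError):
    """Puckering amplitude below the planarity floor: no conformer name."""


class MalformedGlycanError(GlycoValidError):
    """Glycosidic connectivity contains a cycle or other impossibility."""


class MissingCodeError(GlycoValidError):
    """A linkage code is absent from the torsion database."""


class DegenerateDatabaseError(GlycoValidError):
    """Zero bin-count spread: the Z-score is undefined for this linkage."""


class DegenerateReferenceError(GlycoValidError):
    """Reference set has zero spread: quality Z-score undefined."""


class SchemaError(GlycoValidError):
    """Serialized database has an incompatible schema version."""


class InsufficientSampleError(GlycoValidError):
    """Too few observations for the requested statistical test."""


class SpecError(GlycoValidError):
    """A synthetic glycan specification is malformed."""
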