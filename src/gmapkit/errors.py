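"""Exception hierarchy for gmapkit.

All operational failures derive from :class:`GmapError` so callers (and the
CLI) can distinguish domain errors from programming errors.
"""


class GmapError(ValueError):
    """Base class for all gmapkit domain errors."""


class SequenceError(GmapError):
    """Invalid nucleotide sequence (bad alphabet, empty, too short)."""


class SlotError(GmapError):
    """Unknown or inconsistent slot label."""


class PrimerDesignError(GmapError):
    """Template cannot host the requested primer pair."""


class AmplificationError(GmapError):
    """PCR simulation failed: no binding site for a primer."""


class AmbiguousAmplificationError(GmapError):
    """PCR simulation failed: a primer binds more than once."""

    def __init__(self, message: str, positions: list[int]):
        super().__init__(message)
        self.positions = positions


class AssemblyError(GmapError):
    """Base for assembly failures."""


class IncompleteAssemblyError(AssemblyError):
    """No circular product closes; carries the unmatched termini."""

    def __init__(self, message: str, unmatched_sites: list[int]):
        super().__init__(message)
        self.unmatched_sites = unmatched_sites


class AmbiguousAssemblyError(AssemblyError):
    """More than one distinct circular product is possible."""

    def __init__(self, message: str, products: list):
        super().__init__(message)
        self.products = products


class EnzymeError(GmapError):
    """Invalid enzyme definition (bad IUPAC code, unknown name)."""


class FixtureError(GmapError):
    """Fixture generation could not satisfy its constraints."""


class FormatError(GmapError):
    """Malformed sequence file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
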