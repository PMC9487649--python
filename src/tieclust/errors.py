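"""Exception hierarchy.

All parse-time problems derive from :class:`ParseError` so callers (e.g. the
survey runner) can isolate a bad input file without aborting the batch.
"""


class TieclustError(Exception):
    """Base class for all package errors."""


class ParseError(TieclustError, ValueError):
    """A text input could not be parsed into a valid object."""


class GenotypeParseError(ParseError):
    """Malformed genotype table (bad cell, duplicate label, wrong ploidy)."""


class MatrixParseError(ParseError):
    """Malformed proximity matrix text."""


class AsymmetryError(MatrixParseError):
    """Matrix entries (i, j) and (j, i) disagree beyond the printed precision."""


class NoSharedLociError(TieclustError, ValueError):
    """A pair of individuals has no locus typed in both."""


class ZeroSimilarityError(TieclustError, ValueError):
    """-log transform hit similarity 0 and no finite cap was supplied."""
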