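"""Exception types shared across the package."""


class PlastcodonError(Exception):
    """Base class for all package errors."""


class FormatError(PlastcodonError):
    """Malformed or unreadable input file."""


class UndefinedMetricError(PlastcodonError):
    """A statistic is undefined for the given input (e.g. zero denominator).

    Distinct from invalid input: callers assembling per-gene tables catch
    this and flag the gene rather than aborting the run.
    """


class NoQuadripartiteStructure(PlastcodonError):
    """No inverted-repeat pair meeting the thresholds was found.

    Raised only when the caller asks for strict behaviour; the detector
    itself returns None, which commands render as an "NA" row.
    """
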