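"""Exception hierarchy for pbmscan.

All package-specific failures derive from :class:`PbmScanError` so callers can
catch one base class at the CLI boundary.
"""


class PbmScanError(Exception):
    """Base class for all pbmscan errors."""


class ParseError(PbmScanError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ScoreRangeError(PbmScanError):
    """An E-score fell outside the defined [-0.5, 0.5] range."""


class SymmetryError(PbmScanError):
    """An octamer and its reverse complement carry conflicting scores."""


class CompletenessError(PbmScanError):
    """An E-score table is missing octamers after mirror-filling."""


class UnscoreableOctamerError(PbmScanError):
    """An octamer contains a base outside A/C/G/T and has no E-score."""


class ScanError(PbmScanError):
    """A sequence cannot be scanned under the given configuration."""


class FitError(PbmScanError):
    """A regression could not be performed (degenerate or insufficient data)."""


class FixtureError(PbmScanError):
    """A synthetic-fixture specification is unsatisfiable."""
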