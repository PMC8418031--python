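"""Exception hierarchy for polydose."""


class PolydoseError(Exception):
    """Base class for all polydose errors."""


class ParseError(PolydoseError):
    """A delimited input file violated its schema.

    Carries the offending path and (1-based) line number where known.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class IncompletePlateError(PolydoseError):
    """A sample lacks wells for a required assay."""


class InvalidGenotypeError(PolydoseError):
    """A genotype string or allelic configuration is malformed."""


class InfeasibleCrossError(PolydoseError):
    """No feasible gamete-ploidy allocation exists for a cross."""


class DegenerateDataError(PolydoseError):
    """Input data are too small or too degenerate for the requested statistic."""
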