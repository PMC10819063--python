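"""Exception hierarchy shared across the package."""


class PyrethriskError(Exception):
    """Base class for all package-specific errors."""


class UnknownMetaboliteError(PyrethriskError, KeyError):
    """A metabolite identifier is not one of the recognised urinary biomarkers."""


class NoSuchLinkError(PyrethriskError, KeyError):
    """The substance does not excrete the requested metabolite."""


class UnknownSubstanceError(PyrethriskError, KeyError):
    """A substance name is not present in the parameter registry."""


class ConfigurationError(PyrethriskError, ValueError):
    """A configuration value is out of range or inconsistent."""


class AnchorError(PyrethriskError, ValueError):
    """Percentile anchors are non-monotone, non-positive or degenerate."""


class UndefinedFitError(PyrethriskError, ValueError):
    """A regression or distribution fit is undefined for the given data."""


class TableFormatError(PyrethriskError, ValueError):
    """An input table violates the documented schema.

    Carries the per-row error report in ``row_errors`` (list of
    ``(line_number, message)`` tuples) when the failure is row-level.
    """

    def __init__(self, message: str, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])
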