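"""Exception hierarchy shared across the package."""


class IsotraceError(Exception):
    """Base class for all package-specific errors."""


class FormulaError(IsotraceError, ValueError):
    """Malformed chemical formula text."""


class UnknownElementError(IsotraceError, KeyError):
    """Element symbol absent from the isotope abundance table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return f"unknown element symbol {self.symbol!r}: not in the abundance table"


class UnderMeasuredError(IsotraceError, ValueError):
    """Fewer measured channels than labeled states: system is underdetermined."""


class AlreadyCorrectedError(IsotraceError, ValueError):
    """Natural-abundance correction requested on an already corrected dataset."""


class CsvFormatError(IsotraceError, ValueError):
    """Input CSV does not match the documented dialect."""


class SchemaError(IsotraceError, ValueError):
    """Workspace or Escher-map JSON does not match the expected schema."""


class MissingInputError(IsotraceError, ValueError):
    """A graph or analysis prerequisite (time points, standards, ...) is absent."""
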