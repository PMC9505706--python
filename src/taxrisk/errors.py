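"""Exception hierarchy shared across the package."""


class TaxriskError(Exception):
    """Base class for all package errors."""


class LineageParseError(TaxriskError):
    """A taxonomy lineage string could not be parsed."""


class FormatError(TaxriskError):
    """A tabular input file violated its format contract."""


class ConfigError(TaxriskError):
    """An invalid option or parameter value was supplied."""


class ValidationError(TaxriskError):
    """Data failed an internal consistency check."""
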