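"""Exception hierarchy.

All package errors derive from :class:`FhpError` so callers (and the CLI)
can distinguish configuration, data, and numerical failures.
"""


class FhpError(Exception):
    """Base class for all fhpdx errors."""

    category = "error"


class ConfigError(FhpError):
    """Invalid configuration: bad schema, missing file, out-of-range option."""

    category = "config"


class DataError(FhpError):
    """Invalid input data: missing levels, length mismatches, domain violations."""

    category = "data"


class NumericalError(FhpError):
    """Numerical failure: singular covariance, degenerate fit, ordering violation."""

    category = "numerical"
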