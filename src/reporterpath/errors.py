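"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` (and subclasses
raised for malformed data) exit with status 1, :class:`ConfigurationError`
with status 2.
"""


class ReporterPathError(Exception):
    """Base class for all errors raised by reporterpath."""

    exit_code = 1


class InputError(ReporterPathError):
    """Malformed, empty, or inconsistent input data."""

    exit_code = 1


class ValidationError(InputError):
    """A record inside an otherwise readable file violates the format contract."""


class ConfigurationError(ReporterPathError):
    """An option, column mapping, or parameter value is unusable."""

    exit_code = 2
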