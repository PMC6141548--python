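"""Exception hierarchy shared across the pipeline.

Exit codes used by the CLI: usage errors are handled by click (exit 2),
:class:`FormatError`/:class:`VocabularyError` map to exit 3, and
:class:`NumericError` to exit 4.
"""


class CircageError(Exception):
    """Base class for all package errors."""


class FormatError(CircageError):
    """An input file violates its declared dialect (missing columns,
    unparseable fields, inconsistent coordinates). Messages name the
    offending file and line where possible."""


class VocabularyError(CircageError):
    """A categorical field holds a value outside its closed vocabulary
    (brain region, sex, age group)."""


class NumericError(CircageError):
    """A computation cannot proceed (no all-positive row for size factors,
    zero-variance profiles, degenerate designs)."""


class ConfigError(CircageError):
    """A pipeline configuration is incomplete or out of range."""
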