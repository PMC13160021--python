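"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: usage errors exit 2 (handled by click),
:class:`InputError` exits 3, anything else exits 4.
"""


class TaxalignError(Exception):
    """Base class for all errors raised by taxalign."""


class InputError(TaxalignError):
    """Malformed or inconsistent user-supplied input (files, tables, params)."""


class IndexFormatError(InputError):
    """An index file is corrupt, truncated, or of an incompatible version."""
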