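"""Exception taxonomy shared across the pipeline.

``InputError`` marks problems with user-supplied data (malformed tables,
missing files, inconsistent FASTQ mates) and maps to exit code 1 in the CLI;
everything else is an internal error (exit code 2).
"""


class CombiScreenError(Exception):
    """Base class for all package errors."""


class InputError(CombiScreenError):
    """User input is malformed, missing, or inconsistent."""


class DegenerateNullError(CombiScreenError):
    """A null distribution has zero spread and cannot be used for scaling."""
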