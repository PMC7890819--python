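"""Exception hierarchy shared by all pipeline stages.

Each class carries the process exit code the command-line entry points use:
0 success, 2 malformed input, 3 invalid parameters, 4 mid-pipeline failure.
"""


class MarshcazError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class FormatError(MarshcazError):
    """Malformed input data (bad FASTA record, missing table column, ...)."""

    exit_code = 2


class ParameterError(MarshcazError):
    """Invalid configuration or function arguments."""

    exit_code = 3


class PipelineError(MarshcazError):
    """A stage failed mid-run; the message names the stage and context."""

    exit_code = 4


class QuantificationError(MarshcazError):
    """A protein or dataset cannot be quantified (e.g. no observable peptides)."""

    exit_code = 4
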