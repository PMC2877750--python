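"""Exception hierarchy; the CLI maps these onto exit codes (2 input, 3 stats)."""


class MethylskinError(Exception):
    """Base class for package errors."""


class InputError(MethylskinError, ValueError):
    """Malformed or inconsistent user input (exit code 2 in the CLI)."""


class PreconditionError(MethylskinError, RuntimeError):
    """A statistical precondition failed, e.g. no probes survive a filter
    (exit code 3 in the CLI)."""
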