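"""Exception hierarchy shared across the package."""


class TranstatError(Exception):
    """Base class for all errors raised by transtat."""


class ValidationError(TranstatError):
    """Invalid user input: malformed file, violated invariant, bad parameter.

    Maps to CLI exit code 1; any other exception maps to exit code 2.
    """
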