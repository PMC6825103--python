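"""Package-level exception types.

``ValidationError`` marks inputs that violate a documented precondition or
invariant; I/O problems raise the builtin ``OSError`` family.  The CLI maps
these onto exit codes (2 and 3 respectively).
"""


class ValidationError(ValueError):
    """An input violated a documented precondition or data invariant."""
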