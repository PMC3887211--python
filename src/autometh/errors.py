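"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user input: bad sequence, malformed file, out-of-range value."""


class ConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge; message carries the initialization."""
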