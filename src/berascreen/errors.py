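"""Named error types shared across the pipeline."""


class ValidationError(ValueError):
    """Invalid user input, metadata, or configuration (CLI exit code 2)."""


class NumericalError(RuntimeError):
    """Training or linear-algebra failure, e.g. a singular damped system
    or a non-finite objective (CLI exit code 3)."""
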