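"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A configuration or model parameter violates its constraints."""


class GenerationError(RuntimeError):
    """A phantom could not be generated (e.g. lesion target exceeds capacity)."""


class DesignError(ValueError):
    """A resampling-design request is inconsistent with the cohort."""


class InputError(ValueError):
    """An image or record input violates the operation's contract."""
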