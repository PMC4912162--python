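"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped before meeting its tolerance."""


class MultichainWarning(UserWarning):
    """The average-reward gain differs across starting states."""
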