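"""Exception types shared across the analysis modules."""


class DegenerateInputError(ValueError):
    """An input is formally valid but statistically degenerate (e.g. zero variance)."""


class InsufficientDataError(ValueError):
    """Too few observations/subjects to compute the requested quantity."""


class EmDivergenceError(RuntimeError):
    """EM produced non-finite sufficient statistics; carries the iteration index."""

    def __init__(self, message: str, iteration: int):
        super().__init__(f"{message} (iteration {iteration})")
        self.iteration = iteration
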