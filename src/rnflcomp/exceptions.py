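"""Exception hierarchy.

``ContractError`` marks violated call contracts (bad labels, mismatched
lengths, missing covariates); the CLI maps it to exit code 1 and I/O
failures to exit code 2.
"""


class ContractError(ValueError):
    """A precondition or invariant of the public API was violated."""


class ConfigurationError(ContractError):
    """A configuration value is invalid or would produce degenerate data."""


class DivergenceError(RuntimeError):
    """Iterative training produced a non-finite loss."""

    def __init__(self, iteration: int, learning_rate: float):
        self.iteration = iteration
        self.learning_rate = learning_rate
        super().__init__(
            f"non-finite loss at iteration {iteration} "
            f"(learning_rate={learning_rate}); lower the learning rate"
        )
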