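"""Exception hierarchy shared across the package."""


class NeuroarError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(NeuroarError, ValueError):
    """A configuration value violates its contract."""


class DegenerateInputError(NeuroarError, ValueError):
    """Input data is degenerate for the requested operation (e.g. a constant parcel)."""


class ExplosionError(NeuroarError, ArithmeticError):
    """A simulated recursion produced non-finite samples."""

    def __init__(self, time_index: int):
        self.time_index = time_index
        super().__init__(f"non-finite sample first produced at time index {time_index}; "
                         "the coupling matrices are unstable")


class InvalidSplitError(NeuroarError, ValueError):
    """A run split request cannot be satisfied."""


class EmptyWindowSetError(NeuroarError, ValueError):
    """No run was long enough to yield a single supervised window."""


class InsufficientSubjectsError(NeuroarError, ValueError):
    """Too few subjects remain to estimate a cross-subject quantity."""


class ContractError(NeuroarError, ValueError):
    """A model was called with inputs inconsistent with its configuration."""


class DivergenceError(NeuroarError, ArithmeticError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, learning_rate: float):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(f"non-finite training loss at epoch {epoch} "
                         f"(learning rate {learning_rate}); reduce the learning rate")


class NoViableConfigError(NeuroarError, RuntimeError):
    """Every configuration in a grid search diverged."""


class UndefinedScoreError(NeuroarError, ValueError):
    """A score is undefined (e.g. R^2 against a zero-variance target)."""


class AlignmentError(NeuroarError, ValueError):
    """Runs cannot be matched across subjects."""
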