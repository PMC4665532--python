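"""Exception hierarchy for cardioseg.

All data/processing failures derive from :class:`CardiosegError` so the CLI
can map them to a single exit code while usage errors stay separate.
"""


class CardiosegError(Exception):
    """Base class for all cardioseg data and processing errors."""


class IncompleteGridError(CardiosegError):
    """A (slice, phase) cell of the cine grid has no frame."""


class DimensionMismatchError(CardiosegError):
    """Frames or masks do not share identical pixel dimensions."""


class SeedOffObjectError(CardiosegError):
    """The seed kernel contains no object pixel in the overlapped binary image."""

    def __init__(self, row: int, col: int, context: str = ""):
        self.row, self.col = row, col
        msg = f"seed kernel at (row={row}, col={col}) contains no object pixel"
        if context:
            msg += f" [{context}]"
        super().__init__(msg)


class NonConvergenceError(CardiosegError):
    """Iterative threshold selection cycled without reaching a fixpoint."""

    def __init__(self, last: int, previous: int, max_iter: int):
        self.last, self.previous = last, previous
        super().__init__(
            f"threshold did not converge within {max_iter} iterations; "
            f"last two values were {previous} -> {last}"
        )


class ContourError(CardiosegError):
    """Mask is empty or has multiple components; no single boundary exists."""


class BasalOffsetError(CardiosegError):
    """ED and ES slice coverage differ by more than one basal position."""


class DegenerateSeriesError(CardiosegError):
    """A statistic is undefined for the given series (zero variance, constant)."""


class PhantomConfigError(CardiosegError):
    """Synthetic phantom configuration is geometrically or numerically invalid."""
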