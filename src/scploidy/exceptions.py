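"""Package exceptions."""


class ScploidyError(Exception):
    """Base class for scploidy errors."""


class EmptyCellError(ScploidyError):
    """A cell with zero usable reads."""


class TooFewBinsError(ScploidyError):
    """Not enough bins for a trend/model fit."""


class PloidyWindowError(ScploidyError):
    """No candidate ploidy solution inside the allowed window."""


class MixtureFitError(ScploidyError):
    """Constrained mixture optimisation failed; carries best-so-far fit."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class DensityError(ScploidyError):
    """Read-density computation or classification is not possible."""


class SingleEndError(DensityError):
    """Single-end data cannot support the overlap-density method."""
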