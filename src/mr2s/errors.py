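"""Exception hierarchy shared across the package."""


class MRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRError):
    """Bad user configuration: missing columns, invalid parameter values."""


class ValidationError(MRError):
    """Input data violates an invariant (duplicate rsid, bad ordering, ...)."""


class InsufficientInstrumentsError(MRError):
    """Fewer instruments survive selection/harmonization than a method needs."""

    def __init__(self, n_retained: int, n_required: int, context: str = ""):
        self.n_retained = n_retained
        self.n_required = n_required
        msg = f"insufficient instruments: {n_retained} retained, {n_required} required"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class EstimationError(MRError):
    """An estimator could not produce a defined result (e.g. non-convergence)."""
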