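"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A generator or analysis parameter violates its contract."""


class InputError(ValueError):
    """Input data (frames, grids, traces) violates a precondition."""


class FitError(RuntimeError):
    """A model fit (e.g. thin-plate spline) could not be performed."""


class MetricUndefinedError(RuntimeError):
    """A derived metric is undefined for the given data (e.g. too few beats)."""
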