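"""Exception hierarchy for hiddenpop."""


class HiddenPopError(Exception):
    """Base class for all hiddenpop errors."""


class InputError(HiddenPopError):
    """Malformed or unreadable input data (bad columns, unparseable times)."""


class ParameterError(HiddenPopError):
    """Invalid parameter value (M too small, window too short, bad fraction)."""


class EstimationError(HiddenPopError):
    """Numerical failure during estimation (root finder did not converge)."""
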