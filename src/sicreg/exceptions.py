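"""Exception types raised by the fitting machinery."""


class SingularDesignError(ValueError):
    """The design matrix is rank deficient, so OLS initial values do not exist."""


class DegenerateResponseError(ValueError):
    """The response is an exact linear function of the design (s^2 = 0)."""


class NumericalFailure(RuntimeError):
    """Numerical breakdown during optimisation.

    Carries the index of the telescope step at which the failure occurred in
    ``eps_index`` (None when the failure is outside the telescope loop).
    """

    def __init__(self, message: str, eps_index: int | None = None):
        super().__init__(message)
        self.eps_index = eps_index
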