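"""Exception hierarchy for maximum-entropy model fitting."""


class MaxEntError(Exception):
    """Base class for all model errors."""


class FeasibilityError(MaxEntError):
    """A constraint target lies outside the attainable range of its row."""


class ConditioningError(MaxEntError):
    """The constraint set is rank-deficient or the dual Hessian is singular."""


class ConvergenceError(MaxEntError):
    """The dual iteration did not reach the residual tolerance."""


class PanelError(MaxEntError):
    """A territorial panel is malformed (missing rows, duplicates, bad values)."""
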