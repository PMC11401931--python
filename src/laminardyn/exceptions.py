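"""Exception hierarchy.

``ValidationError`` covers bad user input (configs, out-of-range parameters);
``ConstraintError`` covers infeasible design-generation constraints;
``FoldError`` covers cross-validation folds that cannot be constructed.
"""


class LaminarError(Exception):
    """Base class for all package errors."""


class ValidationError(LaminarError, ValueError):
    """Invalid parameter or input contract violation."""


class ConstraintError(LaminarError, RuntimeError):
    """Design constraints could not be satisfied within bounded retries."""


class FoldError(LaminarError, RuntimeError):
    """Cross-validation folds could not be constructed."""


class RankError(LaminarError, RuntimeError):
    """Rank-deficient design matrix; names the aliased regressors."""
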