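"""Package-wide error and warning types."""


class ParameterError(ValueError):
    """A model parameter or state violates its documented bounds."""


class ConfigError(ValueError):
    """A configuration file could not be parsed or validated."""


class DesignError(ValueError):
    """A sweep design is inconsistent (unknown parameter, bad range, ...)."""


class NoBracketError(ValueError):
    """Tipping-point bisection requires end-state classes to differ at the bracket ends."""


class DegenerateTargetError(ValueError):
    """Importance ranking target is constant (or empty) across the sweep."""


class ReplicatorStagnationWarning(RuntimeWarning):
    """Total fitness mass was zero; the replicator step froze the type distribution."""


class NonConvergenceWarning(RuntimeWarning):
    """A run hit the iteration cap without converging and without detectable oscillation."""
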