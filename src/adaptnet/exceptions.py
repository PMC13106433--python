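"""Exception hierarchy for adaptnet."""


class AdaptnetError(Exception):
    """Base class for all adaptnet errors."""


class ParameterError(AdaptnetError, ValueError):
    """Invalid argument or configuration value."""


class BalancingInfeasibleError(AdaptnetError, ValueError):
    """A row cannot be balanced: no nonzero inhibitory entry to rescale."""


class DivergenceError(AdaptnetError, RuntimeError):
    """The simulated state blew up (|x|_inf exceeded the divergence bound)."""

    def __init__(self, t_blowup: float, bound: float = 1e6):
        self.t_blowup = float(t_blowup)
        self.bound = float(bound)
        super().__init__(
            f"state diverged (|x|_inf > {bound:g}) at t = {t_blowup:.6g} s"
        )


class DegeneratePerturbationError(AdaptnetError, RuntimeError):
    """Reference and shadow trajectories collapsed to identical states."""


class UndefinedTestError(AdaptnetError, ValueError):
    """A statistical test is undefined for the given data (e.g. all-zero diffs)."""
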