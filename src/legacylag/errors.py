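"""Exception hierarchy.

All package-specific failures derive from :class:`LegacyLagError` so callers
(and the CLI) can distinguish model errors from programming errors.
"""


class LegacyLagError(Exception):
    """Base class for all legacylag errors."""


class DegenerateParameterError(LegacyLagError, ValueError):
    """Parameter set sits on a manifold where a closed form is undefined.

    The standard two-exponential source function requires Q != lambda*s*n*V;
    on that manifold the amplitude N blows up and the analytic solution takes
    a t*exp(-lambda*t) limit form instead.
    """


class NumericalError(LegacyLagError, RuntimeError):
    """An ODE integration or quadrature failed to converge."""


class TargetNotReachedError(LegacyLagError, RuntimeError):
    """A root search did not find the requested crossing within the horizon."""


class UnreachableTargetError(LegacyLagError, ValueError):
    """Requested concentration reduction exceeds the model's maximum CR_inf."""


class ConfigError(LegacyLagError, ValueError):
    """Run configuration is malformed; the message names the offending key."""
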