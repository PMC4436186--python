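"""Source-zone biogeochemistry: legacy soil-N depletion and the source function.

After land is taken out of row-crop production, the excess (legacy) pool of
mineralizable soil organic nitrogen, ``Mson``, decays as a first-order process
with rate constant ``lambda``.  The mineralized N enters the dissolved pool of
the soil column (water volume ``Vw = n*s*V`` per unit area) and is flushed to
groundwater by the mean annual recharge ``Q``:

    dMson/dt      = -lambda * Mson
    d(Vw*Cs)/dt   =  lambda * Mson - Q * Cs

whose solution is a two-exponential "source function"

    Cs(t) = N exp(-lambda t) + (Cs0 - N) exp(-gamma t),
    N     = lambda * Mson0 / (Q - lambda * s * n * V),
    gamma = Q / (s * n * V),

with ``Cs0`` the pre-change steady-state nitrate concentration.  ``Cs(t)`` is
the leachate concentration feeding every converted stream tube and is the
kernel that the travel-time convolution acts on.

Units: years, metres, g/m^2 areal mass, g/m^3 == mg/L concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DegenerateParameterError, NumericalError, TargetNotReachedError
from .units import kg_per_ha_to_g_per_m2, mm_per_y_to_m_per_y

__all__ = [
    "SourceZoneParams",
    "StepSourceParams",
    "legacy_mass",
    "source_concentration",
    "source_concentration_ode",
    "time_to_source_reduction",
]

#: relative tolerance below which Q - lambda*s*n*V is treated as zero
DEGENERATE_RTOL = 1.0e-10


@dataclass(frozen=True)
class SourceZoneParams:
    """Parameters of the legacy-depletion source function.

    Parameters
    ----------
    mson0 : float
        Initial areal mass of mineralizable legacy soil organic N (g/m^2).
    cs0 : float
        Initial (pre-change steady state) source-zone nitrate-N
        concentration (mg/L, equivalently g/m^3).
    lam : float
        First-order legacy depletion rate constant lambda (1/y); may be 0
        (pure flushing, no organic-pool input).
    q : float
        Mean annual recharge (m/y).
    s : float
        Saturation of the soil column (0-1).
    n : float
        Porosity (0-1).
    v : float
        Soil-column volume per unit area, i.e. depth (m).
    """

    mson0: float
    cs0: float
    lam: float
    q: float
    s: float
    n: float
    v: float

    def __post_init__(self) -> None:
        for name in ("mson0", "cs0", "q", "s", "n", "v"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.s > 1:
            raise ValueError("saturation s must be <= 1")
        if self.n > 1:
            raise ValueError("porosity n must be <= 1")

    @classmethod
    def from_field_units(
        cls,
        *,
        mson0_kg_per_ha: float,
        cs0_mg_per_L: float,
        lambda_per_y: float,
        recharge_mm_per_y: float,
        saturation: float,
        porosity: float,
        depth_m: float,
    ) -> "SourceZoneParams":
        """Build from the units the quantities are usually reported in."""
        return cls(
            mson0=kg_per_ha_to_g_per_m2(mson0_kg_per_ha),
            cs0=cs0_mg_per_L,
            lam=lambda_per_y,
            q=mm_per_y_to_m_per_y(recharge_mm_per_y),
            s=saturation,
            n=porosity,
            v=depth_m,
        )

    # ---- derived quantities -------------------------------------------------

    @property
    def water_volume(self) -> float:
        """Water volume per unit area Vw = n*s*V (m)."""
        return self.n * self.s * self.v

    @property
    def gamma(self) -> float:
        """Flushing rate gamma = Q / (s*n*V) (1/y)."""
        return self.q / self.water_volume

    @property
    def is_degenerate(self) -> bool:
        """True when Q == lambda*s*n*V within tolerance (N undefined)."""
        lsv = self.lam * self.water_volume
        return abs(self.q - lsv) <= DEGENERATE_RTOL * max(self.q, lsv)

    @property
    def n_amp(self) -> float:
        """Amplitude N of the exp(-lambda t) mode (mg/L).

        N = lambda * Mson0 / (Q - lambda*s*n*V); undefined on the degenerate
        manifold Q == lambda*s*n*V.
        """
        if self.is_degenerate:
            raise DegenerateParameterError(
                "Q == lambda*s*n*V: amplitude N is undefined; use "
                "source_concentration(..., degenerate='limit')"
            )
        return self.lam * self.mson0 / (self.q - self.lam * self.water_volume)

    def modes(self) -> tuple[tuple[float, float], ...]:
        """Exponential modes ((amplitude mg/L, rate 1/y), ...) of Cs(t)."""
        n_amp = self.n_amp if self.lam > 0 else 0.0
        return ((n_amp, self.lam), (self.cs0 - n_amp, self.gamma))

    def concentration(self, t):
        """Source function Cs(t); accepts scalars or arrays of years."""
        return source_concentration(t, self)

    @property
    def decays(self) -> bool:
        """Cs(t) -> 0 as t -> infinity (always true for this source)."""
        return True


@dataclass(frozen=True)
class StepSourceParams:
    """Heaviside source: concentration drops from ``cs0`` to ``post`` at t=0.

    This is the no-biogeochemical-legacy idealization: converted parcels stop
    leaching immediately (``post = 0`` by default), so only water already in
    transit (the hydrologic legacy) shapes the outlet trajectory.
    """

    cs0: float
    post: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.cs0) or self.cs0 <= 0:
            raise ValueError("cs0 must be strictly positive")
        if not (0 <= self.post <= self.cs0):
            raise ValueError("post must satisfy 0 <= post <= cs0")

    def modes(self) -> tuple[tuple[float, float], ...]:
        if self.post == 0:
            return ()
        return ((self.post, 0.0),)

    def concentration(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        out = np.full_like(t, self.post, dtype=float)
        return float(out) if out.ndim == 0 else out

    @property
    def decays(self) -> bool:
        return self.post == 0


# ---- operations -------------------------------------------------------------


def legacy_mass(t, params: SourceZoneParams):
    """Remaining legacy soil organic N mass Mson(t) = Mson0 exp(-lambda t).

    Parameters
    ----------
    t : float or array_like
        Years since conversion (>= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = params.mson0 * np.exp(-params.lam * t)
    return float(out) if out.ndim == 0 else out


def source_concentration(t, params: SourceZoneParams, *, degenerate: str = "raise"):
    """Closed-form source function Cs(t) (mg/L).

    Parameters
    ----------
    t : float or array_like
        Years since conversion (>= 0).
    degenerate : {"raise", "limit"}
        On the manifold Q == lambda*s*n*V the two-exponential form is
        undefined.  ``"raise"`` (default) raises
        :class:`~legacylag.errors.DegenerateParameterError`; ``"limit"``
        returns the analytic gamma -> lambda limit
        ``(cs0 + (lambda*mson0/(s*n*v)) * t) * exp(-lambda*t)``.
    """
    if degenerate not in ("raise", "limit"):
        raise ValueError("degenerate must be 'raise' or 'limit'")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if params.lam > 0 and params.is_degenerate:
        if degenerate == "raise":
            raise DegenerateParameterError(
                "Q == lambda*s*n*V: closed form undefined; pass "
                "degenerate='limit' for the analytic limit form"
            )
        slope = params.lam * params.mson0 / params.water_volume
        out = (params.cs0 + slope * t) * np.exp(-params.lam * t)
        return float(out) if out.ndim == 0 else out
    (a1, r1), (a2, r2) = params.modes()
    out = a1 * np.exp(-r1 * t) + a2 * np.exp(-r2 * t)
    return float(out) if out.ndim == 0 else out


def source_concentration_ode(t_grid, params: SourceZoneParams, tol: float = 1.0e-10):
    """Numerically integrate the coupled mass-balance ODEs for Cs(t).

    Serves as an independent check on :func:`source_concentration`: the pair
    dMson/dt = -lambda*Mson, d(Vw*Cs)/dt = lambda*Mson - Q*Cs is integrated
    from (Mson0, Cs0) with an adaptive stiff-capable solver.

    Parameters
    ----------
    t_grid : array_like
        Sorted, nonnegative evaluation times (years).
    tol : float
        Relative tolerance passed to the integrator.

    Returns
    -------
    numpy.ndarray
        Cs at ``t_grid`` (mg/L).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if np.any(t_grid < 0) or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted and nonnegative")
    vw = params.water_volume

    def rhs(_t, y):
        mson, cs = y
        return [-params.lam * mson, (params.lam * mson - params.q * cs) / vw]

    t_end = float(t_grid[-1]) if t_grid[-1] > 0 else 1.0
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [params.mson0, params.cs0],
        method="LSODA",
        t_eval=np.clip(t_grid, 0.0, t_end),
        rtol=tol,
        atol=tol * params.cs0 * 1e-3,
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    return sol.y[1]


def _first_downward_crossing(g, lo: float, hi: float, n_scan: int = 256) -> tuple[float, float] | None:
    """Bracket of the first sign change of g on [lo, hi], scanning linearly."""
    ts = np.linspace(lo, hi, n_scan + 1)
    vals = np.array([g(x) for x in ts])
    sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
    if sign_change.size == 0:
        return None
    i = int(sign_change[0])
    return float(ts[i]), float(ts[i + 1])


def time_to_source_reduction(
    fraction: float, params: SourceZoneParams, *, horizon: float = 1.0e4
) -> float:
    """First time at which Cs(t) has fallen by ``fraction`` of Cs0.

    Solves Cs(t) = (1 - fraction) * Cs0 for the first downward crossing.
    Because Cs may initially rise when the mode amplitude N exceeds Cs0, the
    search scans geometrically expanding brackets and targets the first sign
    change rather than assuming monotonicity.

    Parameters
    ----------
    fraction : float
        Required fractional reduction, strictly between 0 and 1.
    horizon : float
        Maximum time (years) searched before declaring the target unreached.
    """
    from scipy.optimize import brentq

    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    target = (1.0 - fraction) * params.cs0

    def g(t):
        return source_concentration(t, params) - target

    lo = 0.0
    hi = 1.0
    while hi <= horizon:
        bracket = _first_downward_crossing(g, lo, hi)
        if bracket is not None:
            return float(brentq(g, *bracket, xtol=1.0e-8))
        lo, hi = hi, hi * 2.0
    raise TargetNotReachedError(
        f"Cs did not fall to {1 - fraction:.3g}*Cs0 within {horizon:g} years"
    )
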