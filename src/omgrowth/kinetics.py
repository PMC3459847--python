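"""Mean-field growth law and stochastic insertion-event kinetics.

Growth of the cylindrical outer-membrane area is driven by bursty insertion
events governed by three kinetic parameters:

* ``k_on`` — areal initiation rate of insertion events (µm⁻² s⁻¹),
* ``k_ins`` — area insertion rate of one active event (µm² s⁻¹),
* ``tau`` — mean event lifetime (s), exponentially distributed
  (termination is a single kinetic step).

The ensemble average obeys the linear system::

    dA/dt = k_ins · n
    dn/dt = k_on · A − n/τ

whose dominant eigenvalue λ (the positive root of λ² + λ/τ = k_on·k_ins)
sets the exponential growth rate, hence the doubling time
t_double = ln2/λ. Fixing t_double therefore pins τ given (k_on, k_ins):
τ = λ/(k_on·k_ins − λ²). Along the dominant eigenvector the concentration
of active sites is constant, n/A = λ/k_ins, and the mean area inserted per
event is τ·k_ins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "KineticParams",
    "MeanFieldState",
    "InfeasibleGrowthError",
    "solve_tau",
    "growth_rate",
    "meanfield_trajectory",
    "sample_events",
    "time_step",
]

LN2 = math.log(2.0)


class InfeasibleGrowthError(ValueError):
    """The requested doubling time cannot be reached for these rates."""


def growth_rate(k_on: float, k_ins: float, tau: float) -> float:
    """Dominant growth exponent λ (s⁻¹): positive root of λ² + λ/τ = k_on·k_ins."""
    return 0.5 * (-1.0 / tau + math.sqrt(1.0 / tau**2 + 4.0 * k_on * k_ins))


def solve_tau(k_on: float, k_ins: float, t_double: float) -> float:
    """Mean event duration τ (s) enforcing a given doubling time.

    Requires k_on·k_ins > (ln2/t_double)²; otherwise even permanently
    active events (τ → ∞) cannot sustain the requested growth rate.
    """
    if k_on <= 0 or k_ins <= 0 or t_double <= 0:
        raise ValueError("k_on, k_ins and t_double must be positive")
    lam = LN2 / t_double
    denom = k_on * k_ins - lam * lam
    if denom <= 0:
        raise InfeasibleGrowthError(
            f"k_on*k_ins = {k_on * k_ins:.3e} <= (ln2/t_double)^2 = "
            f"{lam * lam:.3e}: no positive tau can reach this doubling time"
        )
    return lam / denom


@dataclass(frozen=True)
class KineticParams:
    """The kinetic triple (k_on, k_ins, τ) plus the implied doubling time."""

    k_on: float
    k_ins: float
    tau: float

    def __post_init__(self) -> None:
        if min(self.k_ins, self.tau) <= 0:
            raise ValueError("k_ins and tau must be strictly positive")
        if self.k_on < 0:
            raise ValueError("k_on must be non-negative")

    @classmethod
    def from_doubling_time(
        cls, k_on: float, k_ins: float, t_double: float
    ) -> "KineticParams":
        return cls(k_on, k_ins, solve_tau(k_on, k_ins, t_double))

    @property
    def growth_rate(self) -> float:
        return growth_rate(self.k_on, self.k_ins, self.tau)

    @property
    def t_double(self) -> float:
        lam = self.growth_rate
        return LN2 / lam if lam > 0 else math.inf

    @property
    def mean_event_area(self) -> float:
        """Mean area inserted per event, τ·k_ins (µm²) — the patchiness scale."""
        return self.tau * self.k_ins

    @property
    def steady_site_concentration(self) -> float:
        """Active-site concentration n/A on the dominant eigenvector (µm⁻²)."""
        return self.growth_rate / self.k_ins


@dataclass
class MeanFieldState:
    """Mean-field state: cylindrical OM area A (µm²) and active-site count n."""

    A: float
    n: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("area must be positive")
        if self.n < 0:
            raise ValueError("site count must be non-negative")


def _system_matrix(params: KineticParams) -> np.ndarray:
    return np.array(
        [[0.0, params.k_ins], [params.k_on, -1.0 / params.tau]], dtype=float
    )


def meanfield_trajectory(
    state0: MeanFieldState, params: KineticParams, times: Sequence[float]
) -> list[MeanFieldState]:
    """Exact solution of the mean-field system at the requested times.

    Uses the matrix exponential of the 2×2 system (not a discretized
    integration), so the result is exact to rounding.
    """
    M = _system_matrix(params)
    v0 = np.array([state0.A, state0.n], dtype=float)
    out = []
    for t in times:
        if t < 0:
            raise ValueError("times must be non-negative")
        A, n = expm(M * t) @ v0
        out.append(MeanFieldState(A=float(A), n=float(max(n, 0.0))))
    return out


def sample_events(
    area: float, dt: float, params: KineticParams, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    """Sample insertion-event initiations over one time step.

    Returns the number of new events, Poisson with mean ``k_on·area·dt``,
    and their lifetimes, exponential with mean τ. Positions are assigned by
    the caller (uniform over the cylindrical region).
    """
    if area < 0 or dt <= 0:
        raise ValueError("area must be >= 0 and dt > 0")
    n_new = int(rng.poisson(params.k_on * area * dt))
    durations = rng.exponential(params.tau, size=n_new)
    return n_new, durations


def time_step(params: KineticParams, area: float, max_dt: float = 0.5) -> float:
    """Simulation time step honouring the event-duration sampling rule.

    dt = min(τ/20, 1/(20·k_on·A), max_dt): at least ~20 steps per mean
    event lifetime and per mean initiation interval, capped at ``max_dt``
    (0.5 s default), keeping discretization bias in event statistics well
    below the stochastic spread.
    """
    dt = min(params.tau / 20.0, max_dt)
    if params.k_on > 0 and area > 0:
        dt = min(dt, 1.0 / (20.0 * params.k_on * area))
    return dt
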