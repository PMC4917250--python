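"""Well-mixed (mean-field) dynamics of the Jungle game.

Densities x1..x5 live on the probability 4-simplex and evolve under the
pairwise zero-sum replicator equations

    dx_i/dt = x_i * sum_j M[i, j] * x_j,       M = K - K^T,

where K is the rate matrix of the invasion network.  Every invasion event
K[i,j]*x_i*x_j moves mass from prey to predator, so the total density is
conserved exactly.

The module also exposes the Lyapunov functions of the three 3-species
regimes and the conserved quantity of the five-species regime as
diagnostics: along any trajectory V grows monotonically in its regime,
and V4/V5 is constant in the coexistence regime.  These are the analytic
facts behind :func:`junglegame.core.classify_survivors`;
:func:`ode_survivors` is the empirical cross-check that integrates the
dynamics and reads the survivor set off the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import (
    InvasionNetwork,
    SurvivorSet,
    classify_survivors,
    invariants,
)

__all__ = [
    "UNIFORM_STATE",
    "Trajectory",
    "rhs",
    "integrate",
    "lyapunov_V",
    "conserved_quantity",
    "ode_survivors",
    "IntegrationError",
]

#: Default interior initial condition: all five densities equal.
UNIFORM_STATE = np.full(5, 0.2)

_SIMPLEX_TOL = 1e-12


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the time reached."""

    def __init__(self, message: str, t_reached: float):
        super().__init__(f"{message} (time reached: {t_reached})")
        self.t_reached = t_reached


def _check_state(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (5,):
        raise ValueError("state must have five densities")
    if np.any(x < 0):
        raise ValueError("densities must be non-negative")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"densities must sum to 1, got {x.sum()!r}")
    return x


@dataclass
class Trajectory:
    """Sampled solution of the mean-field equations.

    ``states[k]`` is the (renormalized) simplex state at ``times[k]``;
    ``max_drift`` records the largest |sum(x) - 1| observed before
    renormalization, a solver-quality diagnostic.
    """

    times: np.ndarray
    states: np.ndarray  # shape (n_samples, 5)
    network: InvasionNetwork
    max_drift: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, 5):
            raise ValueError("states must align with times")

    def to_text(self, header: str = "") -> str:
        """Delimited text: columns t, x1..x5, preceded by '#' header
        lines naming the provenance."""
        lines = [f"# {line}" for line in header.splitlines() if line]
        lines.append("t\tx1\tx2\tx3\tx4\tx5")
        for t, x in zip(self.times, self.states):
            lines.append("\t".join([f"{t:.10g}"] + [f"{v:.10g}" for v in x]))
        return "\n".join(lines) + "\n"


def rhs(state: Sequence[float], net: InvasionNetwork) -> np.ndarray:
    """The five time-derivatives of the densities.

    Pairwise zero-sum: the components always sum to zero algebraically
    (mass lost by prey equals mass gained by predator).
    """
    x = np.asarray(state, dtype=float)
    K = net.matrix()
    M = K - K.T
    return x * (M @ x)


def integrate(
    state0: Sequence[float],
    net: InvasionNetwork,
    t_end: float,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-12,
    n_samples: int = 1001,
    method: str = "DOP853",
) -> Trajectory:
    """Integrate the mean-field equations from ``state0`` to ``t_end``.

    Sampled states are clipped at zero (only for negatives smaller in
    magnitude than a guard band of 100*(abs_tol + rel_tol) — anything
    larger signals a solver failure) and renormalized onto the simplex.
    The pre-
    renormalization drift |sum(x)-1| is tracked and must stay below 1e-8
    at the default tolerances.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    x0 = _check_state(np.asarray(state0, dtype=float))
    K = net.matrix()
    M = K - K.T

    def f(t: float, x: np.ndarray) -> np.ndarray:
        return x * (M @ x)

    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(
        f, (0.0, t_end), x0, method=method, t_eval=t_eval,
        rtol=rel_tol, atol=abs_tol,
    )
    if not sol.success:
        t_reached = sol.t[-1] if sol.t.size else 0.0
        raise IntegrationError(sol.message, t_reached)
    states = sol.y.T.copy()
    neg = states.min()
    # guard band: sampled states come from the solver's interpolant, whose
    # overshoot near an absorbing boundary is governed by rel_tol as well
    # as abs_tol
    if neg < -100 * (abs_tol + rel_tol):
        raise IntegrationError(
            f"density went negative beyond tolerance ({neg})", float(sol.t[-1])
        )
    np.clip(states, 0.0, None, out=states)
    sums = states.sum(axis=1)
    max_drift = float(np.abs(sums - 1.0).max())
    states /= sums[:, None]
    return Trajectory(sol.t, states, net, max_drift)


# ---------------------------------------------------------------------------
# Lyapunov diagnostics for the three 3-species regimes
# ---------------------------------------------------------------------------

# case -> (species carrying the exponents, exponent rate pairs, growth row)
# case 1 (A>0, B>0):  V  = x1^K25 * x2^K51 * x5^K12,  dV/dt = V*( A*x3 + B*x4)
# case 2 (A<0, C>0):  V2 = x1^K35 * x3^K51 * x5^K13,  dV/dt = V*(-A*x2 + C*x4)
# case 3 (B<0, C<0):  V3 = x1^K45 * x4^K51 * x5^K14,  dV/dt = V*(-B*x2 - C*x3)
_CASES = {
    1: dict(species=(1, 2, 5), exps=((2, 5), (5, 1), (1, 2))),
    2: dict(species=(1, 3, 5), exps=((3, 5), (5, 1), (1, 3))),
    3: dict(species=(1, 4, 5), exps=((4, 5), (5, 1), (1, 4))),
}


def _case_precondition(case: int, A: float, B: float, C: float) -> str | None:
    """Return a message naming the failing sign condition, or None."""
    if case == 1:
        if not (A > 0 and B > 0):
            return f"case 1 requires A>0 and B>0, got A={A}, B={B}"
    elif case == 2:
        if not (A < 0 and C > 0):
            return f"case 2 requires A<0 and C>0, got A={A}, C={C}"
    elif case == 3:
        if not (B < 0 and C < 0):
            return f"case 3 requires B<0 and C<0, got B={B}, C={C}"
    else:
        raise ValueError(f"case must be 1, 2 or 3, got {case}")
    return None


def lyapunov_V(
    state: Sequence[float], net: InvasionNetwork, case: int
) -> tuple[float, float]:
    """Value and instantaneous growth rate of the regime's Lyapunov
    function.

    Returns ``(V, dV/dt)``.  Under the case's sign precondition the growth
    is non-negative everywhere on the simplex, so V increases along
    trajectories until the two doomed species have died out (LaSalle's
    invariance principle: the set where growth vanishes is the invariant
    face on which they are absent).
    """
    x = _check_state(state)
    inv = invariants(net)
    msg = _case_precondition(case, inv.A, inv.B, inv.C)
    if msg is not None:
        raise ValueError(msg)
    cfg = _CASES[case]
    V = 1.0
    for sp, (ei, ej) in zip(cfg["species"], cfg["exps"]):
        V *= x[sp - 1] ** net.rate(ei, ej)
    if case == 1:
        growth = V * (inv.A * x[2] + inv.B * x[3])
    elif case == 2:
        growth = V * (-inv.A * x[1] + inv.C * x[3])
    else:
        growth = V * (-inv.B * x[1] - inv.C * x[2])
    return float(V), float(growth)


def conserved_quantity(state: Sequence[float], net: InvasionNetwork) -> float:
    """The motion invariant of the five-species coexistence regime.

    For A>0 this is V4 = x1^E * x2^C * x3^(-B) * x4^A * x5^D; for A<0 the
    exponents flip sign (V5).  In either branch all exponents are
    positive, so the quantity is positive on the simplex interior and
    vanishes only on the boundary (a monoculture gives 0).  It is exactly
    conserved by the dynamics — (E, C, -B, A, D) is a null vector of
    K - K^T.
    """
    x = _check_state(state)
    if classify_survivors(net) is not SurvivorSet.ALL_FIVE:
        raise ValueError(
            "conserved quantity is defined only in the five-species "
            "coexistence regime (AB<0 and AC>0)"
        )
    inv = invariants(net)
    exps = np.array([inv.E, inv.C, -inv.B, inv.A, inv.D])
    if inv.A < 0:
        exps = -exps
    # Appendix sign lemmas guarantee positivity of every exponent here.
    if np.any(x == 0):
        return 0.0
    return float(np.prod(x ** exps))


def _integrate_log(
    x0: np.ndarray,
    net: InvasionNetwork,
    t_end: float,
    rel_tol: float,
    abs_tol: float,
    n_samples: int,
) -> Trajectory:
    """Integrate in log-density space, y_i = log x_i.

    dy/dt = M exp(y) is globally Lipschitz on the simplex, densities stay
    positive by construction, and the asymptotic exponential decay of an
    extinct species becomes a benign linear drift of y — no step-size
    underflow near the absorbing boundary.  Requires an interior start.
    """
    if np.any(x0 <= 0):
        raise ValueError("log-space integration needs an interior state")
    K = net.matrix()
    M = K - K.T

    def f(t: float, y: np.ndarray) -> np.ndarray:
        # densities never legitimately exceed 1 (y <= 0); the cap only
        # tames solver trial steps so exp cannot overflow
        return M @ np.exp(np.minimum(y, 5.0))

    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(
        f, (0.0, t_end), np.log(x0), method="DOP853", t_eval=t_eval,
        rtol=rel_tol, atol=abs_tol,
    )
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else 0.0)
    states = np.exp(sol.y.T)
    sums = states.sum(axis=1)
    max_drift = float(np.abs(sums - 1.0).max())
    states /= sums[:, None]
    return Trajectory(sol.t, states, net, max_drift)


def ode_survivors(
    net: InvasionNetwork,
    t_end: float | None = None,
    extinction_threshold: float = 1e-3,
    state0: Sequence[float] | None = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    n_samples: int = 2001,
) -> SurvivorSet:
    """Read the survivor set off an integrated trajectory.

    The network is first rescaled so its largest rate is 1 (time-scale
    covariance makes this a pure change of time unit), then integrated
    from the interior start to ``t_end`` in log-density space.  A species
    is declared extinct when its maximum density over the trailing half of
    the samples falls below ``extinction_threshold`` — finite-time ODE
    extinction is asymptotic, so a trailing-window maximum separates
    decaying species from oscillating survivors.  The window is the
    trailing half of the trajectory: near regime boundaries the surviving
    trio settles onto a large-amplitude cycle whose low-density dwells
    can last a sizable fraction of the run, and a narrower window can
    miss the cycle's high phase.

    The default horizon is 500 time units, stretched when the smallest of
    |A|, |B|, |C| (in the rescaled rates) is small: the average decay rate
    of a doomed species is proportional to that invariant, so near a
    regime boundary the dynamics simply needs longer to sort itself out.
    """
    x0 = UNIFORM_STATE if state0 is None else np.asarray(state0, float)
    unit_net = net.scaled(1.0 / max(net.rates))
    if t_end is None:
        inv = invariants(unit_net)
        min_inv = min(abs(inv.A), abs(inv.B), abs(inv.C))
        t_end = max(500.0, 30.0 / max(min_inv, 1e-6))
    # If the alive set is not one of the four admissible survivor sets the
    # window has under-sampled a long-period cycle (survivors can dwell at
    # astronomically low densities on large-amplitude cycles); the limit
    # cycle's period is finite, so doubling the horizon until the window
    # covers it resolves the read-out.
    for _ in range(7):
        traj = _integrate_log(
            x0, unit_net, t_end, rel_tol=rel_tol, abs_tol=abs_tol,
            n_samples=n_samples,
        )
        tail = traj.states[traj.times.size // 2:]
        alive = tuple(
            sp for sp in range(1, 6)
            if tail[:, sp - 1].max() >= extinction_threshold
        )
        for member in SurvivorSet:
            if member.species == alive:
                return member
        t_end *= 2.0
    return SurvivorSet.BOUNDARY
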