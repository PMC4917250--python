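"""Seeded generators of networks, states and small lattices.

Everything here is a pure function of its seed and constraints, so the
whole test surface of the package runs with no external input.  Rates are
drawn log-uniformly on [0.1, 10]: this spans two decades, exercises the
scale invariance of the classifier, and produces both signs of A, B and C
with good probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TOPOLOGY, InvasionNetwork, classify_survivors, invariants, make_network
from .lattice import Lattice

__all__ = [
    "FixtureSpec",
    "random_network",
    "case_network",
    "interior_state",
    "enumerable_lattice",
]

_REJECTION_BUDGET = 100_000


def random_network(seed: int, margin: float = 0.0) -> InvasionNetwork:
    """Random valid network with min(|A|, |B|, |C|) > margin.

    Rates are log-uniform on [0.1, 10]; draws are rejected until the
    margin holds, so margin > 0 guarantees a classifiable (non-BOUNDARY)
    network.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    rng = np.random.default_rng(seed)
    for _ in range(_REJECTION_BUDGET):
        rates = 10.0 ** rng.uniform(-1.0, 1.0, size=10)
        net = InvasionNetwork(tuple(rates))
        inv = invariants(net)
        if min(abs(inv.A), abs(inv.B), abs(inv.C)) > margin:
            return net
    raise RuntimeError(
        f"rejection budget exhausted for margin={margin}"
    )


def _case_holds(case: int, A: float, B: float, C: float) -> bool:
    if case == 1:
        return A > 0 and B > 0
    if case == 2:
        return A < 0 and C > 0
    if case == 3:
        return B < 0 and C < 0
    if case == 4:
        return A * B < 0 and A * C > 0
    raise ValueError(f"case must be 1, 2, 3 or 4, got {case}")


def case_network(case: int, seed: int, margin: float = 0.05) -> InvasionNetwork:
    """Random network satisfying one of the four sign regimes.

    Case 1: A>0, B>0 (trio S1,S2,S5); case 2: A<0, C>0 (S1,S3,S5);
    case 3: B<0, C<0 (S1,S4,S5); case 4: AB<0, AC>0 (all five).
    """
    _case_holds(case, 1.0, 1.0, 1.0)  # validate case id eagerly
    rng = np.random.default_rng(seed)
    for _ in range(_REJECTION_BUDGET):
        sub_seed = int(rng.integers(0, 2 ** 31))
        net = random_network(sub_seed, margin=margin)
        inv = invariants(net)
        if _case_holds(case, inv.A, inv.B, inv.C):
            return net
    raise RuntimeError(f"rejection budget exhausted for case {case}")


def interior_state(seed: int, min_density: float = 0.01) -> np.ndarray:
    """Random interior simplex state with every density >= min_density."""
    rng = np.random.default_rng(seed)
    while True:
        x = rng.dirichlet(np.ones(5))
        if x.min() >= min_density:
            return x


_PATTERNS = {
    # one S1 at the center, eight S2
    "one-invader": np.array(
        [[2, 2, 2], [2, 1, 2], [2, 2, 2]], dtype=np.int8
    ),
    # alternating rows of S4 and S5
    "two-species-stripe": np.array(
        [[4, 4, 4], [5, 5, 5], [4, 4, 4]], dtype=np.int8
    ),
    # three species tiling the nine sites
    "checker-of-three": np.array(
        [[1, 2, 3], [3, 1, 2], [2, 3, 1]], dtype=np.int8
    ),
}


def enumerable_lattice(pattern: str) -> Lattice:
    """Deterministic named 3x3 lattice for the one-step enumeration
    oracle.  Patterns: one-invader, two-species-stripe, checker-of-three."""
    try:
        return Lattice(_PATTERNS[pattern].copy())
    except KeyError:
        raise ValueError(
            f"unknown pattern {pattern!r}; choose from {sorted(_PATTERNS)}"
        ) from None


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative handle on a generator: (kind, seed, constraints) fully
    determine the fixture."""

    kind: str  # random-network | case-conditioned-network | interior-state | small-lattice
    seed: int = 0
    constraints: dict = field(default_factory=dict)

    def generate(self):
        if self.kind == "random-network":
            return random_network(self.seed, **self.constraints)
        if self.kind == "case-conditioned-network":
            return case_network(seed=self.seed, **self.constraints)
        if self.kind == "interior-state":
            return interior_state(self.seed, **self.constraints)
        if self.kind == "small-lattice":
            return enumerable_lattice(**self.constraints)
        raise ValueError(f"unknown fixture kind {self.kind!r}")
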