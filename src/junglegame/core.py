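"""Domain types for the five-species Jungle game.

The Jungle game ranks five species S1 (strongest) to S5 (weakest).  Every
species invades all lower-ranked species it can reach, and the bottom
species S5 invades only the top species S1.  The interaction topology is
therefore a fixed tournament on ten directed predator->prey pairs::

    S1 -> S2, S3, S4
    S2 -> S3, S4, S5
    S3 -> S4, S5
    S4 -> S5
    S5 -> S1

Each directed pair carries a strictly positive invasion rate ``K[i, j]``
(the rate at which species i replaces species j upon encounter).  Three
degree-2 combinations of the rates,

    A = K13*K25 + K23*K51 - K12*K35
    B = K14*K25 + K24*K51 - K12*K45
    C = K14*K35 + K34*K51 - K13*K45

determine the asymptotic survivor set of the well-mixed dynamics whenever
none of them vanishes: A>0, B>0 gives the trio {S1,S2,S5}; A<0, C>0 gives
{S1,S3,S5}; B<0, C<0 gives {S1,S4,S5}; AB<0 with AC>0 lets all five
species coexist.  Two further combinations D and E supply the exponents of
the conserved quantity in the five-species regime.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "TOPOLOGY",
    "InvasionNetwork",
    "CoexistenceInvariants",
    "SurvivorSet",
    "make_network",
    "example1_network",
    "example2_network",
    "invariants",
    "classify_survivors",
]

#: The ten directed predator->prey pairs of the Jungle tournament (1-based).
TOPOLOGY: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (1, 4),
    (2, 3), (2, 4), (2, 5),
    (3, 4), (3, 5),
    (4, 5),
    (5, 1),
)

_TOPOLOGY_SET = frozenset(TOPOLOGY)


@dataclass(frozen=True)
class InvasionNetwork:
    """A validated assignment of positive invasion rates to the topology.

    Construct via :func:`make_network`, :func:`example1_network` or
    :func:`example2_network`; the constructor itself performs the same
    validation so direct use is safe but less convenient.
    """

    rates: tuple[float, ...]  # aligned with TOPOLOGY order

    def __post_init__(self) -> None:
        if len(self.rates) != len(TOPOLOGY):
            raise ValueError(
                f"expected {len(TOPOLOGY)} rates, got {len(self.rates)}"
            )
        object.__setattr__(self, "rates", tuple(float(k) for k in self.rates))
        for pair, k in zip(TOPOLOGY, self.rates):
            if not (k > 0) or not math.isfinite(k):
                raise ValueError(
                    f"rate for pair K_{pair[0]},{pair[1]} must be a finite "
                    f"positive real, got {k!r}"
                )

    def rate(self, i: int, j: int) -> float:
        """Rate at which species i invades species j; (i, j) must be a
        topology pair."""
        try:
            return self.rates[TOPOLOGY.index((i, j))]
        except ValueError:
            raise KeyError(f"({i}, {j}) is not a predation pair of the Jungle topology") from None

    def as_dict(self) -> dict[tuple[int, int], float]:
        return dict(zip(TOPOLOGY, self.rates))

    def matrix(self) -> np.ndarray:
        """5x5 rate matrix K with K[i-1, j-1] = rate(i, j) and zeros on
        the structurally absent pairs (for numeric kernels only — zero
        here encodes 'no edge', never 'rate zero')."""
        K = np.zeros((5, 5))
        for (i, j), k in zip(TOPOLOGY, self.rates):
            K[i - 1, j - 1] = k
        return K

    def scaled(self, lam: float) -> "InvasionNetwork":
        """All ten rates multiplied by ``lam`` > 0 (a pure change of time
        unit in the mean-field dynamics)."""
        if not lam > 0:
            raise ValueError("scale factor must be positive")
        return InvasionNetwork(tuple(k * lam for k in self.rates))

    # -- flat key-value serialization -------------------------------------

    def to_text(self) -> str:
        """One line per pair, ``K_i_j = <repr>``; round-trip exact."""
        lines = [
            f"K_{i}_{j} = {k!r}" for (i, j), k in zip(TOPOLOGY, self.rates)
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "InvasionNetwork":
        rates: dict[tuple[int, int], float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            parts = key.strip().split("_")
            if len(parts) != 3 or parts[0] != "K":
                raise ValueError(f"unparseable network line: {line!r}")
            rates[(int(parts[1]), int(parts[2]))] = float(value)
        return make_network(rates)


def make_network(rates: Mapping[tuple[int, int], float]) -> InvasionNetwork:
    """Build a validated :class:`InvasionNetwork` from a mapping of the ten
    directed pairs to positive rates.

    Raises ``ValueError`` naming the offending pair if a topology pair is
    missing, an off-topology pair is supplied, or a rate is not strictly
    positive.
    """
    extra = set(rates) - _TOPOLOGY_SET
    if extra:
        i, j = sorted(extra)[0]
        raise ValueError(f"pair ({i}, {j}) is not in the Jungle topology")
    missing = _TOPOLOGY_SET - set(rates)
    if missing:
        i, j = sorted(missing)[0]
        raise ValueError(f"missing rate for topology pair ({i}, {j})")
    return InvasionNetwork(tuple(float(rates[p]) for p in TOPOLOGY))


def example1_network(p: float, s: float) -> InvasionNetwork:
    """Two-parameter food-preference family.

    Primary food (the next-lower level) is eaten at rate 1: K[i,i+1] = 1
    for i = 1..4.  Every other prey is "sub-food", eaten at a single rate
    ``p``: K13 = K14 = K24 = K25 = K35 = p.  The bottom-to-top inhibition
    is K51 = s.  Under this family A = C = p^2 - p + s and
    B = p^2 + s*p - 1.
    """
    if not p > 0:
        raise ValueError(f"p must be positive, got {p}")
    if not s > 0:
        raise ValueError(f"s must be positive, got {s}")
    rates = {pair: 1.0 for pair in ((1, 2), (2, 3), (3, 4), (4, 5))}
    rates.update({pair: float(p) for pair in ((1, 3), (1, 4), (2, 4), (2, 5), (3, 5))})
    rates[(5, 1)] = float(s)
    return make_network(rates)


def example2_network(p1: float, p2: float, s: float) -> InvasionNetwork:
    """Three-parameter family splitting sub-food into second- and
    third-level prey.

    K[i,i+1] = 1 (primary food), K[i,i+2] = p1 for i = 1,2,3 (secondary),
    K[i,i+3] = p2 for i = 1,2 (tertiary), K51 = s.  Under this family
    A = C = p1*p2 + s - p1 and B = p2^2 + p1*s - 1, so the A = 0 curve in
    the (p2, s) plane is the line s = p1*(1 - p2) and the B = 0 curve is
    the parabola s = (1 - p2^2)/p1.
    """
    for name, v in (("p1", p1), ("p2", p2), ("s", s)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    rates = {pair: 1.0 for pair in ((1, 2), (2, 3), (3, 4), (4, 5))}
    rates.update({pair: float(p1) for pair in ((1, 3), (2, 4), (3, 5))})
    rates.update({pair: float(p2) for pair in ((1, 4), (2, 5))})
    rates[(5, 1)] = float(s)
    return make_network(rates)


@dataclass(frozen=True)
class CoexistenceInvariants:
    """The five degree-2 rate combinations controlling coexistence."""

    A: float
    B: float
    C: float
    D: float
    E: float

    def sign_pattern(self, tol: float = 0.0) -> tuple[int, int, int]:
        """Signs of (A, B, C); 0 marks magnitudes at or below ``tol``."""
        def sgn(v: float) -> int:
            if abs(v) <= tol:
                return 0
            return 1 if v > 0 else -1

        return (sgn(self.A), sgn(self.B), sgn(self.C))


def invariants(net: InvasionNetwork) -> CoexistenceInvariants:
    """Compute A, B, C, D, E from the network's rates."""
    K = net.rate
    A = K(1, 3) * K(2, 5) + K(2, 3) * K(5, 1) - K(1, 2) * K(3, 5)
    B = K(1, 4) * K(2, 5) + K(2, 4) * K(5, 1) - K(1, 2) * K(4, 5)
    C = K(1, 4) * K(3, 5) + K(3, 4) * K(5, 1) - K(1, 3) * K(4, 5)
    D = K(1, 4) * K(2, 3) + K(1, 2) * K(3, 4) - K(1, 3) * K(2, 4)
    E = K(2, 3) * K(4, 5) + K(2, 5) * K(3, 4) - K(2, 4) * K(3, 5)
    return CoexistenceInvariants(A, B, C, D, E)


class SurvivorSet(enum.Enum):
    """The asymptotic survivor set predicted by the sign pattern of
    (A, B, C).

    The four strict-sign conditions partition all eight sign patterns:
    exactly one applies to each.  ``BOUNDARY`` is returned only when
    |A|, |B| or |C| falls below the classification tolerance — on the
    measure-zero boundary curves the analysis makes no prediction.
    """

    S1S2S5 = (1, 2, 5)
    S1S3S5 = (1, 3, 5)
    S1S4S5 = (1, 4, 5)
    ALL_FIVE = (1, 2, 3, 4, 5)
    BOUNDARY = ()

    @property
    def species(self) -> tuple[int, ...]:
        """Member species (1-based); empty for BOUNDARY."""
        return self.value


def default_boundary_tol(net: InvasionNetwork) -> float:
    """Default tolerance below which A, B or C counts as zero: 1e-12
    relative to max(rate)^2, since A-E are degree-2 polynomials in the
    rates."""
    return 1e-12 * max(net.rates) ** 2


def classify_survivors(
    net: InvasionNetwork, tol: float | None = None
) -> SurvivorSet:
    """Predict the asymptotic survivor set of the well-mixed dynamics.

    ``tol`` defaults to :func:`default_boundary_tol`; any of |A|, |B|, |C|
    at or below it yields ``SurvivorSet.BOUNDARY``.
    """
    if tol is None:
        tol = default_boundary_tol(net)
    inv = invariants(net)
    sA, sB, sC = inv.sign_pattern(tol)
    if 0 in (sA, sB, sC):
        return SurvivorSet.BOUNDARY
    if sA > 0 and sB > 0:
        return SurvivorSet.S1S2S5
    if sA < 0 and sC > 0:
        return SurvivorSet.S1S3S5
    if sB < 0 and sC < 0:
        return SurvivorSet.S1S4S5
    # remaining patterns satisfy AB < 0 and AC > 0
    return SurvivorSet.ALL_FIVE
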