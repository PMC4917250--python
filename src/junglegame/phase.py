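"""Parameter-plane region maps and the coexistence-area analysis.

For the two-parameter family (:func:`junglegame.core.example1_network`)
the (p, s) plane splits into three regions separated by the curves
A = C = 0 (s = p - p^2) and B = 0 (s = 1/p - p): the trio {S1,S2,S5}
above both curves (region I), five-species coexistence between them
(region II), and the trio {S1,S4,S5} below both (region III).

For the three-parameter family with p1 fixed, the (p2, s) plane contains
the line A = 0: s = p1*(1 - p2) and the parabola B = 0:
s = (1 - p2^2)/p1.  The area between them inside the unit p2-strip,

    Area(p1) = integral_0^1 | p1*(1 - p2) - (1 - p2^2)/p1 | dp2,

measures how much of the (p2, s) plane supports five-species coexistence.
The two curves cross inside the strip at p2 = p1^2 - 1 exactly when
1 < p1 < sqrt(2); on that interval the integral has the closed form

    Area(p1) = -p1^5/3 + 2*p1^3 - (7/2)*p1 + 2/p1,

which attains its minimum at p1 = P with P ~ 1.149 (P^2 is the relevant
root of 10*x^3 - 36*x^2 + 21*x + 12 = 0).  Area is strictly decreasing
for p1 <= 1 and strictly increasing for p1 >= sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .core import (
    SurvivorSet,
    classify_survivors,
    example1_network,
    example2_network,
)

__all__ = [
    "RegionMap",
    "region_map_example1",
    "region_map_example2",
    "area_closed_form",
    "area_numeric",
    "minimize_area",
    "area_monotonicity_check",
]

SQRT2 = math.sqrt(2.0)

#: Region labels of the printed phase diagrams, keyed by survivor set.
REGION_ROMAN = {
    SurvivorSet.S1S2S5: "I",
    SurvivorSet.ALL_FIVE: "II",
    SurvivorSet.S1S4S5: "III",
}


@dataclass
class RegionMap:
    """Survivor-set labels on a rectangular grid of a parameter plane."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    labels: np.ndarray  # object array of SurvivorSet, shape (len1, len2)
    parameterization: str

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, float)
        self.axis2 = np.asarray(self.axis2, float)
        if self.labels.shape != (self.axis1.size, self.axis2.size):
            raise ValueError("label grid dimensions must match the axes")

    def save_png(self, path: str) -> None:
        """Raster with the conventional region legend: region I
        (S1S2S5) green, region II (all five) white, region III (S1S4S5)
        yellow; the off-diagram S1S3S5 set blue, boundaries grey."""
        from matplotlib import pyplot as plt
        from matplotlib.colors import ListedColormap

        order = [
            SurvivorSet.S1S2S5, SurvivorSet.ALL_FIVE, SurvivorSet.S1S4S5,
            SurvivorSet.S1S3S5, SurvivorSet.BOUNDARY,
        ]
        colors = ["#2ca02c", "#ffffff", "#ffdf00", "#1f77b4", "#888888"]
        idx = np.vectorize(order.index)(self.labels)
        plt.imsave(path, idx.T[::-1], cmap=ListedColormap(colors),
                   vmin=0, vmax=4)

    def to_text(self) -> str:
        """Delimited label matrix with axis header lines."""
        lines = [
            f"# parameterization: {self.parameterization}",
            "# " + self.axis1_name + ": "
            + " ".join(f"{v:.10g}" for v in self.axis1),
            "# " + self.axis2_name + ": "
            + " ".join(f"{v:.10g}" for v in self.axis2),
        ]
        for row in self.labels:
            lines.append("\t".join(lab.name for lab in row))
        return "\n".join(lines) + "\n"


def region_map_example1(
    p_grid: Sequence[float], s_grid: Sequence[float]
) -> RegionMap:
    """Classify every (p, s) cell of the two-parameter family."""
    p_grid = np.asarray(p_grid, float)
    s_grid = np.asarray(s_grid, float)
    labels = np.empty((p_grid.size, s_grid.size), dtype=object)
    for a, p in enumerate(p_grid):
        for b, s in enumerate(s_grid):
            labels[a, b] = classify_survivors(example1_network(p, s))
    return RegionMap("p", p_grid, "s", s_grid, labels, "example1")


def region_map_example2(
    p1: float, p2_grid: Sequence[float], s_grid: Sequence[float]
) -> RegionMap:
    """Classify every (p2, s) cell of the three-parameter family at
    fixed p1.  For p2 >= 1 every s yields the trio {S1,S2,S5}."""
    p2_grid = np.asarray(p2_grid, float)
    s_grid = np.asarray(s_grid, float)
    labels = np.empty((p2_grid.size, s_grid.size), dtype=object)
    for a, p2 in enumerate(p2_grid):
        for b, s in enumerate(s_grid):
            labels[a, b] = classify_survivors(example2_network(p1, p2, s))
    return RegionMap(
        "p2", p2_grid, "s", s_grid, labels, f"example2(p1={p1:g})"
    )


def area_closed_form(p1: float) -> float:
    """Closed form of the coexistence area, valid on 1 < p1 < sqrt(2)."""
    if not (1.0 < p1 < SQRT2):
        raise ValueError(
            f"closed form is valid only for 1 < p1 < sqrt(2), got {p1}"
        )
    return -p1 ** 5 / 3.0 + 2.0 * p1 ** 3 - 3.5 * p1 + 2.0 / p1


def area_numeric(p1: float) -> float:
    """Adaptive quadrature of |p1*(1-p2) - (1-p2^2)/p1| over p2 in [0,1].

    Valid for every p1 > 0; serves as the oracle for all three branches.
    The interior kink at p2 = p1^2 - 1 (present when 1 < p1 < sqrt(2)) is
    passed to the integrator as a breakpoint.
    """
    if not p1 > 0:
        raise ValueError("p1 must be positive")

    def integrand(p2: float) -> float:
        return abs(p1 * (1.0 - p2) - (1.0 - p2 ** 2) / p1)

    kink = p1 ** 2 - 1.0
    points = [kink] if 0.0 < kink < 1.0 else None
    value, _ = quad(integrand, 0.0, 1.0, points=points, epsabs=1e-12, limit=200)
    return value


def minimize_area() -> tuple[float, float]:
    """Minimize the closed-form area over (1, sqrt(2)).

    Returns ``(P, Area(P))``; P ~ 1.149, the sub-food-to-primary-food
    rate ratio that leaves the least room for five-species coexistence.
    """
    res = minimize_scalar(
        area_closed_form,
        bounds=(1.0 + 1e-12, SQRT2 - 1e-12),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x), float(res.fun)


def area_monotonicity_check(
    p1_grid: Sequence[float], h: float = 1e-6
) -> dict[float, float]:
    """Central-difference slope of the numeric area at each grid point.

    Returns {p1: slope}.  Slopes are negative throughout p1 <= 1 and
    positive throughout p1 >= sqrt(2); grid points should stay at least
    1e-3 away from the branch boundaries 1 and sqrt(2) so the stencil
    does not straddle a kink in the derivative.
    """
    report: dict[float, float] = {}
    for p1 in np.asarray(p1_grid, float):
        slope = (area_numeric(p1 + h) - area_numeric(p1 - h)) / (2.0 * h)
        report[float(p1)] = float(slope)
    return report
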