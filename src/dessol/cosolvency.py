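"""DES-water cosolvency analysis.

Adding water to a deep eutectic solvent first raises the solubility of a
hydrophobic solute and then, past an optimal composition, lowers it
again — an apparent cosolvency/antisolvency effect.  This module
locates the optimal solute-free DES mole fraction x*_DES on a measured
curve, computes enhancement ratios against the neat DES or a named
reference solvent, and quantifies temperature gains between matched
compositions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CosolvencyCurve",
    "CosolvencyResult",
    "find_optimum",
    "quadratic_refine",
    "enhancement_ratio",
    "temperature_gain",
    "analyze_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CosolvencyCurve:
    """Solubility versus solute-free DES mole fraction at one temperature."""

    system_label: str
    temperature: float
    points: tuple[tuple[float, float], ...]  # (x_star_des, x_solubility)

    def __post_init__(self) -> None:
        pts = tuple((float(a), float(b)) for a, b in self.points)
        xs = [a for a, _ in pts]
        if any(not (0.0 <= a <= 1.0) for a in xs):
            raise ValueError("x_star_des must lie in [0, 1]")
        if any(b <= 0.0 or b >= 1.0 for _, b in pts):
            raise ValueError("solubilities must lie in (0, 1)")
        if not all(x1 < x2 for x1, x2 in zip(xs, xs[1:])):
            raise ValueError("x_star_des must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def x_star(self) -> np.ndarray:
        return np.array([a for a, _ in self.points])

    @property
    def x_solubility(self) -> np.ndarray:
        return np.array([b for _, b in self.points])

    @property
    def reference_neat(self) -> float | None:
        """Solubility at x*_DES = 1 (the water-free DES), if measured."""
        for a, b in self.points:
            if a == 1.0:
                return b
        return None


@dataclass(frozen=True)
class CosolvencyResult:
    """Located optimum and enhancement ratios for one cosolvency curve."""

    system_label: str
    temperature: float
    x_star_optimal: float
    x_at_optimal: float
    enhancement_vs_neat_percent: int | None
    comparison_vs_reference: float | None
    interior_optimum: bool
    x_star_refined: float | None = None


def find_optimum(curve: CosolvencyCurve) -> tuple[float, float]:
    """Grid point of maximal solubility on a cosolvency curve.

    Ties resolve to the larger DES fraction (with a warning).  A maximum
    sitting on the boundary of the composition grid is flagged via the
    module logger; :func:`analyze_curve` reports it structurally.
    """
    if len(curve.points) < 3:
        raise ValueError("need at least 3 points to locate an optimum")
    ys = curve.x_solubility
    xs = curve.x_star
    best = ys.max()
    idx = np.flatnonzero(ys == best)
    if len(idx) > 1:
        logger.warning(
            "tie at maximum solubility on %s; taking the larger x*_DES",
            curve.system_label,
        )
    i = int(idx[-1])
    if i in (0, len(ys) - 1):
        logger.info(
            "no interior optimum on %s: maximum at the grid boundary "
            "x* = %g", curve.system_label, xs[i],
        )
    return float(xs[i]), float(ys[i])


def quadratic_refine(curve: CosolvencyCurve) -> tuple[float, float]:
    """Vertex of the parabola through the grid maximum and its neighbours.

    Diagnostic only — the grid optimum is what gets reported.  Falls
    back to the grid point when the maximum sits on the boundary or the
    three points are collinear/concave-up.
    """
    xs, ys = curve.x_star, curve.x_solubility
    i = int(np.flatnonzero(ys == ys.max())[-1])
    if i in (0, len(ys) - 1):
        return float(xs[i]), float(ys[i])
    x0, x1, x2 = xs[i - 1], xs[i], xs[i + 1]
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    # Lagrange quadratic through three points; vertex of a x^2 + b x + c.
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0.0:
        return float(x1), float(y1)
    xv = -b / (2.0 * a)
    c = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c)


def enhancement_ratio(x_at_optimal: float, x_neat: float) -> int:
    """Solubility at the optimum as an integer percent of a reference.

    Rounds to the nearest integer, halves away from zero — matching how
    such enhancements are conventionally quoted (e.g. 107.7% -> 108%).
    """
    if x_neat <= 0:
        raise ValueError("reference solubility must be positive")
    v = 100.0 * x_at_optimal / x_neat
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def temperature_gain(
    records_t1: Mapping[float, float],
    records_t2: Mapping[float, float],
) -> tuple[dict[float, float], float]:
    """Percent solubility change between two temperatures, per composition.

    ``records_t1``/``records_t2`` map composition (x*_DES) to solubility
    at the lower/higher temperature.  Compositions must match pairwise.
    Returns the per-composition percent changes and their mean.
    """
    unmatched = set(records_t1) ^ set(records_t2)
    if unmatched:
        raise ValueError(
            f"compositions present at only one temperature: {sorted(unmatched)}"
        )
    gains = {
        comp: 100.0 * (records_t2[comp] - records_t1[comp]) / records_t1[comp]
        for comp in sorted(records_t1)
    }
    mean = float(np.mean(list(gains.values()))) if gains else float("nan")
    return gains, mean


def analyze_curve(
    curve: CosolvencyCurve,
    reference_solubility: float | None = None,
    refine: bool = False,
) -> CosolvencyResult:
    """Full cosolvency analysis of one curve.

    ``reference_solubility`` is the solubility in a named comparison
    solvent (e.g. DMSO); when given, the ratio of the optimum to it is
    reported.
    """
    x_star, x_at = find_optimum(curve)
    interior = x_star not in (curve.x_star[0], curve.x_star[-1])
    neat = curve.reference_neat
    enh = enhancement_ratio(x_at, neat) if neat is not None else None
    comp = (
        x_at / reference_solubility if reference_solubility else None
    )
    refined = quadratic_refine(curve)[0] if refine else None
    return CosolvencyResult(
        system_label=curve.system_label,
        temperature=curve.temperature,
        x_star_optimal=x_star,
        x_at_optimal=x_at,
        enhancement_vs_neat_percent=enh,
        comparison_vs_reference=comp,
        interior_optimum=interior,
        x_star_refined=refined,
    )
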