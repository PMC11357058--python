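"""Solid-liquid equilibrium thermodynamics of the solute.

Dissolving a crystalline solid requires overcoming the fusion
thermodynamics of the crystal.  With melting temperature ``T_m``, fusion
enthalpy ``dH_fus`` and the heat-capacity change on melting ``dC_p``,
the Schroeder-van Laar equation gives the ideal mole-fraction solubility

    ln x = -(dH_fus/R) (1/T - 1/T_m) + (dC_p/R) [T_m/T - 1 - ln(T_m/T)]

which becomes the classical van't Hoff expression for dC_p = 0.  Real
solubility corrects the ideal value with an activity-coefficient model
f(x); here the activity model is an injected callable (unit coefficients
by default), so the solver stays independent of any particular
activity-coefficient engine.

For ferulic acid the fusion data are T_m = 445.83 K and dH_fus = 32.49
kJ/mol; when no measured dC_p is available the common estimate
dC_p ~ dS_fus = dH_fus / T_m is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

__all__ = [
    "R_GAS",
    "FERULIC_ACID_FUSION",
    "FusionProperties",
    "ActivityPoint",
    "AffinityResult",
    "fusion_entropy",
    "ideal_solubility",
    "real_solubility",
    "affinity_delta_g",
    "ConvergenceError",
]

#: Molar gas constant, J/(mol K).
R_GAS = 8.314462618


class ConvergenceError(RuntimeError):
    """Fixed-point iteration for real solubility failed to converge."""

    def __init__(self, message: str, last_iterate: float, residual: float):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


@dataclass(frozen=True)
class FusionProperties:
    """Fusion data of a crystalline solute.

    Attributes
    ----------
    t_melt : float
        Melting temperature, K.
    dh_fus : float
        Enthalpy of fusion, J/mol.
    dcp_fus : float or None
        Heat-capacity change on melting, J/(mol K); ``None`` means
        "estimate on demand".
    """

    t_melt: float
    dh_fus: float
    dcp_fus: float | None = None

    def __post_init__(self) -> None:
        if self.t_melt <= 0:
            raise ValueError("t_melt must be positive")
        if self.dh_fus <= 0:
            raise ValueError("dh_fus must be positive")
        if self.dcp_fus is not None and self.dcp_fus < 0:
            raise ValueError("dcp_fus must be non-negative")


#: Ferulic acid fusion data (compilation average).
FERULIC_ACID_FUSION = FusionProperties(t_melt=445.83, dh_fus=32490.0)


def fusion_entropy(fp: FusionProperties) -> float:
    """Entropy of fusion dS_fus = dH_fus / T_m, J/(mol K).

    Doubles as the default estimate of the fusion heat-capacity change
    (dC_p ~ dS_fus), a standard approximation when calorimetric dC_p is
    unavailable.
    """
    return fp.dh_fus / fp.t_melt


def _resolve_dcp(fp: FusionProperties, dcp_mode: str) -> float:
    if dcp_mode == "zero":
        return 0.0
    if dcp_mode == "fusion_entropy":
        return fusion_entropy(fp)
    if dcp_mode == "explicit":
        if fp.dcp_fus is None:
            raise ValueError("dcp_mode='explicit' requires dcp_fus to be set")
        return fp.dcp_fus
    raise ValueError(f"unknown dcp_mode {dcp_mode!r}")


def ideal_solubility(
    fp: FusionProperties, temperature: float, dcp_mode: str = "zero"
) -> float:
    """Ideal mole-fraction solubility from the Schroeder-van Laar equation.

    Parameters
    ----------
    fp
        Fusion properties of the solute.
    temperature
        Temperature in kelvin; must satisfy 0 < T <= T_m.
    dcp_mode
        ``"zero"`` (van't Hoff limit), ``"fusion_entropy"``
        (dC_p = dH_fus/T_m), or ``"explicit"`` (use ``fp.dcp_fus``).
    """
    T = float(temperature)
    if T <= 0:
        raise ValueError("temperature must be positive kelvin")
    if T > fp.t_melt:
        raise ValueError(
            f"temperature {T} K exceeds the melting point {fp.t_melt} K; "
            "the solid phase does not exist there"
        )
    dcp = _resolve_dcp(fp, dcp_mode)
    tm = fp.t_melt
    ln_x = -(fp.dh_fus / R_GAS) * (1.0 / T - 1.0 / tm)
    if dcp != 0.0:
        ln_x += (dcp / R_GAS) * (tm / T - 1.0 - math.log(tm / T))
    return min(1.0, math.exp(ln_x))


def real_solubility(
    fp: FusionProperties,
    temperature: float,
    activity_model: Callable[[float], float] | None = None,
    dcp_mode: str = "zero",
    tol: float = 1e-10,
    max_iter: int = 500,
    damping: float = 0.5,
) -> float:
    """Mole-fraction solubility with an activity-coefficient correction.

    Solves ``x * f(x) = a_solid`` where ``a_solid`` is the ideal-solution
    activity fixed by the fusion data (i.e. the ideal solubility) and
    ``f`` maps a trial mole fraction to the solute's activity coefficient
    at saturation.  Damped fixed-point iteration:

        x <- (1 - d) * x + d * min(1, a_solid / f(x))

    With the default unit-coefficient model this returns
    :func:`ideal_solubility` exactly.

    Raises
    ------
    ConvergenceError
        If the relative change does not drop below ``tol`` within
        ``max_iter`` iterations; carries the last iterate and residual.
    """
    a_solid = ideal_solubility(fp, temperature, dcp_mode=dcp_mode)
    if activity_model is None:
        return a_solid
    x = a_solid
    for _ in range(max_iter):
        f = activity_model(x)
        if not (f > 0.0 and math.isfinite(f)):
            raise ValueError(
                f"activity model returned non-positive/non-finite {f} at x={x}"
            )
        target = min(1.0, a_solid / f)
        x_new = (1.0 - damping) * x + damping * target
        if abs(x_new - x) <= tol * max(abs(x_new), 1e-300):
            return x_new
        x = x_new
    residual = abs(x * activity_model(x) - a_solid)
    raise ConvergenceError(
        f"real_solubility did not converge in {max_iter} iterations "
        f"(last x = {x}, residual = {residual})",
        last_iterate=x,
        residual=residual,
    )


@dataclass(frozen=True)
class ActivityPoint:
    """Mole fraction, activity coefficient and activity of one species."""

    mole_fraction: float
    activity_coefficient: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mole_fraction <= 1.0):
            raise ValueError("mole fraction must lie in (0, 1]")
        if self.activity_coefficient <= 0:
            raise ValueError("activity coefficient must be positive")

    @property
    def activity(self) -> float:
        """a = x * f."""
        return self.mole_fraction * self.activity_coefficient


@dataclass(frozen=True)
class AffinityResult:
    """Standard Gibbs free energy of pair affinity at one temperature."""

    pair_label: str
    delta_g: float
    temperature: float


def affinity_delta_g(
    a: ActivityPoint, temperature: float, pair_label: str = ""
) -> AffinityResult:
    """Affinity free energy dG = R T ln(a) from an activity point.

    Negative for activities below 1 (thermodynamically favourable
    association), zero at unit activity.
    """
    act = a.activity
    if act <= 0:
        raise ValueError("activity must be positive")
    dg = R_GAS * float(temperature) * math.log(act)
    return AffinityResult(
        pair_label=pair_label, delta_g=dg, temperature=float(temperature)
    )


def load_fusion_config(cfg: dict) -> tuple[FusionProperties, str]:
    """Build fusion properties from a config mapping.

    Expected keys: ``t_melt_K``, ``dh_fus_kJ_mol``, ``dcp_mode`` and
    optionally ``dcp_J_molK``.  Energies cross the I/O boundary in
    kJ/mol and are held internally in J/mol.
    """
    fp = FusionProperties(
        t_melt=float(cfg["t_melt_K"]),
        dh_fus=float(cfg["dh_fus_kJ_mol"]) * 1000.0,
        dcp_fus=float(cfg["dcp_J_molK"]) if "dcp_J_molK" in cfg else None,
    )
    return fp, str(cfg.get("dcp_mode", "zero"))
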