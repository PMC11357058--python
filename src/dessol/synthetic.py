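"""Synthetic sigma-potentials, solubility records and cosolvency curves.

Every pipeline stage needs data with known ground truth: smooth
sigma-potential curves with hydrogen-bond tails and a linear temperature
dependence, solubility values generated from a known linear function of
sigma-region descriptors plus Gaussian noise, and bell-shaped DES-water
cosolvency curves with a known optimum.  This module provides all three
as pure functions of a :class:`GeneratorConfig`, so the full corpus is
reproducible bit for bit from the seed.

The generator targets the *statistical* structure the modelling assumes
(signal located in the hydrogen-bond donor/acceptor tails, log-linear
descriptor-solubility relation, multiplicative temperature gain); it
makes no claim of quantum-chemical fidelity.

Synthetic sigma-potential of a pure compound::

    mu(sigma) = a + b*sigma + c*sigma^2
              + d_don * exp(-(sigma + 0.015)^2 / w_don)
              + d_acc * exp(-(sigma - 0.015)^2 / w_acc)
              + t_slope * (T - 298.15)

and log-solubility of a record::

    log10 x = intercept + sum_r w_r * mean(relative_mu over region r)
            + N(0, noise_sigma)

with x clipped to (1e-6, 0.5).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .cosolvency import CosolvencyCurve
from .data import (
    DesignSpec,
    SolubilityRecord,
    aqueous_des_system,
    des_system,
    enumerate_design,
    make_record_id,
)
from .sigma import (
    SIGMA_GRID,
    SigmaGrid,
    SigmaRegionPartition,
    SolventSystem,
    relative_potential,
)

__all__ = [
    "ShapeParams",
    "GeneratorConfig",
    "generate_sigma_grid",
    "generate_grid_library",
    "generate_solubility",
    "generate_cosolvency",
    "generate_corpus",
    "region_means",
    "true_log10_solubility",
    "ground_truth",
]

SOLUTE_ID = "FA"
T_REF = 298.15


@dataclass(frozen=True)
class ShapeParams:
    """Shape of one compound's synthetic sigma-potential curve."""

    a: float = 0.0          # baseline
    b: float = 0.0          # slope
    c: float = 0.0          # curvature
    d_don: float = 0.0      # donor-tail depth (sigma = -0.015)
    w_don: float = 4e-5     # donor-tail width
    d_acc: float = 0.0      # acceptor-tail depth (sigma = +0.015)
    w_acc: float = 4e-5     # acceptor-tail width
    t_slope: float = 0.0    # linear temperature coefficient, per K


#: Fixed shape parameters for the named compounds of the study, so the
#: packaged defaults are stable fixtures rather than seed-derived.
DEFAULT_SHAPES: dict[str, ShapeParams] = {
    "FA": ShapeParams(a=1.0, b=12.0, c=250.0, d_don=-1.6, d_acc=-1.1,
                      t_slope=-0.002),
    "water": ShapeParams(a=0.4, b=-18.0, c=320.0, d_don=2.1, d_acc=2.4,
                         t_slope=0.001),
    "ChCl": ShapeParams(a=0.6, b=-8.0, c=150.0, d_don=0.9, d_acc=-1.4,
                        t_slope=-0.001),
    "BI": ShapeParams(a=0.7, b=-6.0, c=170.0, d_don=1.1, d_acc=-1.0,
                      t_slope=-0.001),
    "ETG": ShapeParams(a=0.5, b=4.0, c=200.0, d_don=-0.6, d_acc=0.8,
                       t_slope=0.0005),
    "DEG": ShapeParams(a=0.45, b=5.0, c=180.0, d_don=-0.9, d_acc=0.6,
                       t_slope=0.0005),
    "TEG": ShapeParams(a=0.4, b=6.0, c=160.0, d_don=-1.2, d_acc=0.5,
                       t_slope=0.0005),
    "GLY": ShapeParams(a=0.55, b=3.0, c=220.0, d_don=-0.8, d_acc=1.0,
                       t_slope=0.0008),
    "P2D": ShapeParams(a=0.5, b=2.0, c=190.0, d_don=-0.3, d_acc=0.7,
                       t_slope=0.0005),
    "B3D": ShapeParams(a=0.48, b=2.5, c=185.0, d_don=-0.4, d_acc=0.65,
                       t_slope=0.0005),
    # neat literature solvents
    "DMSO": ShapeParams(a=0.3, b=9.0, c=140.0, d_don=-1.5, d_acc=0.2,
                        t_slope=0.0004),
    "transcutol": ShapeParams(a=0.35, b=7.0, c=150.0, d_don=-1.2, d_acc=0.4,
                              t_slope=0.0004),
    "methanol": ShapeParams(a=0.4, b=1.0, c=210.0, d_don=-0.5, d_acc=0.9,
                            t_slope=0.0006),
    "propylene_glycol": ShapeParams(a=0.5, b=2.0, c=195.0, d_don=-0.35,
                                    d_acc=0.7, t_slope=0.0005),
    "ethanol": ShapeParams(a=0.38, b=2.0, c=190.0, d_don=-0.45, d_acc=0.8,
                           t_slope=0.0006),
    "ethylene_glycol": ShapeParams(a=0.5, b=4.0, c=205.0, d_don=-0.55,
                                   d_acc=0.85, t_slope=0.0005),
    "isopropanol": ShapeParams(a=0.36, b=1.5, c=185.0, d_don=-0.4, d_acc=0.75,
                               t_slope=0.0006),
    "2-butanol": ShapeParams(a=0.33, b=1.2, c=175.0, d_don=-0.35, d_acc=0.7,
                             t_slope=0.0006),
    "1-butanol": ShapeParams(a=0.32, b=1.0, c=170.0, d_don=-0.3, d_acc=0.68,
                             t_slope=0.0006),
    "ethyl_acetate": ShapeParams(a=0.25, b=6.0, c=130.0, d_don=0.5, d_acc=-0.3,
                                 t_slope=0.0004),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines the synthetic corpus.

    ``true_weights`` maps sigma-region names to the coefficients of the
    log-linear solubility law; ``noise_sigma`` is the standard deviation
    of the Gaussian noise on log10 x.  Cosolvency defaults emulate the
    study conditions: a peak at x*_DES = 0.7, 10 compositions per curve
    and a +20% multiplicative 25 -> 40 deg C gain.
    """

    seed: int = 0
    sigma_curve_params: dict = field(
        default_factory=lambda: dict(DEFAULT_SHAPES)
    )
    true_weights: dict = field(
        default_factory=lambda: {"HBD": 0.9, "HYD": -1.3, "HBA": 0.5}
    )
    intercept: float = -2.2
    noise_sigma: float = 0.05
    design: DesignSpec = field(default_factory=DesignSpec)
    partition: SigmaRegionPartition = field(
        default_factory=SigmaRegionPartition
    )
    compositions_per_curve: int = 10
    cosolvency_peak: float = 0.7
    cosolvency_height: float = 0.12
    cosolvency_width: float = 0.02
    temperature_factor_25_40: float = 1.20

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _compound_rng(seed: int, compound: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(compound.encode())])


def _shape_for(cfg: GeneratorConfig, compound: str) -> ShapeParams:
    params = cfg.sigma_curve_params.get(compound)
    if params is not None:
        return params
    # unknown compound: deterministic seed-derived shape
    rng = _compound_rng(cfg.seed, compound)
    return ShapeParams(
        a=rng.uniform(0.2, 1.0),
        b=rng.uniform(-15.0, 15.0),
        c=rng.uniform(100.0, 350.0),
        d_don=rng.uniform(-2.0, 2.0),
        d_acc=rng.uniform(-2.0, 2.0),
        t_slope=rng.uniform(-2e-3, 2e-3),
    )


def generate_sigma_grid(
    cfg: GeneratorConfig, compound: str, temperature: float = T_REF
) -> SigmaGrid:
    """Synthetic pure-compound sigma-potential at one temperature."""
    p = _shape_for(cfg, compound)
    s = SIGMA_GRID
    mu = (
        p.a + p.b * s + p.c * s * s
        + p.d_don * np.exp(-((s + 0.015) ** 2) / p.w_don)
        + p.d_acc * np.exp(-((s - 0.015) ** 2) / p.w_acc)
        + p.t_slope * (temperature - T_REF)
    )
    return SigmaGrid(
        compound_id=compound,
        temperature=float(temperature),
        sigma_values=SIGMA_GRID.copy(),
        mu_values=mu,
    )


def generate_grid_library(
    cfg: GeneratorConfig,
    compounds: list[str],
    temperatures: list[float],
) -> list[SigmaGrid]:
    """Grids for every (compound, temperature) combination."""
    return [
        generate_sigma_grid(cfg, c, t)
        for c in compounds for t in temperatures
    ]


def region_means(
    relative_mu: np.ndarray, partition: SigmaRegionPartition
) -> dict[str, float]:
    """Mean relative potential over each sigma region."""
    masks = partition.region_masks()
    return {
        name: float(np.mean(np.asarray(relative_mu)[m]))
        for name, m in masks.items()
    }


def true_log10_solubility(
    cfg: GeneratorConfig, system: SolventSystem, temperature: float
) -> float:
    """Noise-free log10 solubility of the generator's linear law."""
    compounds = [SOLUTE_ID] + [c for c, _ in system.components]
    grids = [generate_sigma_grid(cfg, c, temperature) for c in compounds]
    solute = grids[0]
    desc = relative_potential(solute, system, grids[1:], temperature)
    means = region_means(desc.relative_mu, cfg.partition)
    return cfg.intercept + sum(
        w * means[r] for r, w in cfg.true_weights.items()
    )


def _record_noise(cfg: GeneratorConfig, key: str) -> float:
    if cfg.noise_sigma == 0.0:
        return 0.0
    rng = np.random.default_rng([cfg.seed, 7, zlib.crc32(key.encode())])
    return float(rng.normal(0.0, cfg.noise_sigma))


X_CLIP = (1e-6, 0.5)


def generate_solubility(
    cfg: GeneratorConfig,
    systems: list[SolventSystem],
    temperatures: list[float],
    source: str = "this_work",
) -> list[SolubilityRecord]:
    """Solubility records for every system at every temperature.

    Noise is keyed per record, so the value of a record does not depend
    on which other records are generated alongside it.
    """
    out = []
    for system in systems:
        for T in temperatures:
            log10x = true_log10_solubility(cfg, system, T)
            key = f"{system.label}|{T:.4f}"
            log10x += _record_noise(cfg, key)
            x = float(np.clip(10.0 ** log10x, X_CLIP[0], X_CLIP[1]))
            out.append(SolubilityRecord(
                record_id=make_record_id(SOLUTE_ID, system.label, T, source),
                solute_id=SOLUTE_ID,
                system=system,
                temperature=float(T),
                x_solubility=x,
                source=source,
                class_tag=system.class_tag,
            ))
    return out


def generate_cosolvency(
    cfg: GeneratorConfig,
    system_label: str = "ChCl-TEG 1:2",
    temperature: float = T_REF,
    x_neat: float = 0.0532,
) -> CosolvencyCurve:
    """Bell-shaped DES-water cosolvency curve with a known optimum.

    The 25 deg C curve is ``x(x*) = x_neat * [1 + h exp(-(x* - x_peak)^2
    / w)]`` normalised so that ``x(1) = x_neat``; curves at higher
    temperatures scale the whole curve by the 25->40 deg C factor raised
    to the fractional temperature distance, so matched-composition
    temperature gains are exact by construction.
    """
    n = cfg.compositions_per_curve
    grid = np.linspace(0.1, 1.0, n)
    bump = 1.0 + cfg.cosolvency_height * np.exp(
        -((grid - cfg.cosolvency_peak) ** 2) / cfg.cosolvency_width
    )
    norm = 1.0 + cfg.cosolvency_height * np.exp(
        -((1.0 - cfg.cosolvency_peak) ** 2) / cfg.cosolvency_width
    )
    tfactor = cfg.temperature_factor_25_40 ** ((temperature - T_REF) / 15.0)
    ys = x_neat * bump / norm * tfactor
    return CosolvencyCurve(
        system_label=system_label,
        temperature=float(temperature),
        points=tuple(zip(grid.tolist(), ys.tolist())),
    )


# Corpus composition emulating the documented dataset make-up: 11 neat
# systems / 103 records, 1 binary system / 45 records, and 196 DES
# records = 36 neat DES at 25 degC + 4 aqueous systems x 10 compositions
# x 4 temperatures.
_NEAT_SOLVENTS = (
    "DMSO", "transcutol", "methanol", "propylene_glycol", "ethanol",
    "ethylene_glycol", "isopropanol", "2-butanol", "1-butanol",
    "ethyl_acetate", "water",
)
_NEAT_COUNTS = (10, 10, 10, 10, 9, 9, 9, 9, 9, 9, 9)  # sums to 103


def generate_corpus(cfg: GeneratorConfig) -> list[SolubilityRecord]:
    """The full synthetic modelling corpus (344 records).

    Neat literature solvents contribute temperature series, the single
    binary system (isopropanol-water) a composition x temperature grid,
    and the DES block the 36-system design screen plus the four selected
    aqueous DES curves at the four study temperatures.
    """
    records: list[SolubilityRecord] = []
    # neat solvents: per-solvent temperature series
    for solvent, count in zip(_NEAT_SOLVENTS, _NEAT_COUNTS):
        temps = np.linspace(278.15, 323.15, count)
        system = SolventSystem.neat(solvent)
        records.extend(
            generate_solubility(cfg, [system], temps.tolist(),
                                source="literature")
        )
    # binary aqueous mixture: 9 compositions x 5 temperatures
    for frac in np.linspace(0.1, 0.9, 9):
        system = SolventSystem(
            components=(("isopropanol", float(frac)),
                        ("water", float(1.0 - frac))),
            label=f"isopropanol-water (x={frac:.1f})",
            class_tag="binary",
        )
        records.extend(
            generate_solubility(
                cfg, [system],
                np.linspace(283.15, 323.15, 5).tolist(),
                source="literature",
            )
        )
    # DES screen: all 36 systems at 25 degC
    records.extend(
        generate_solubility(cfg, enumerate_design(cfg.design), [T_REF])
    )
    # aqueous DES curves: 4 systems x 10 compositions x 4 temperatures
    comps = np.linspace(0.1, 1.0, cfg.compositions_per_curve)
    for hba, hbd, n in cfg.design.selected_aqueous_systems:
        systems = [
            aqueous_des_system(hba, hbd, n, float(xs)) for xs in comps
        ]
        records.extend(
            generate_solubility(cfg, systems, list(cfg.design.temperatures))
        )
    return records


def ground_truth(cfg: GeneratorConfig) -> dict:
    """The generator's ground truth, for test harnesses and export."""
    return {
        "seed": cfg.seed,
        "true_weights": dict(cfg.true_weights),
        "intercept": cfg.intercept,
        "noise_sigma": cfg.noise_sigma,
        "cosolvency_peak": cfg.cosolvency_peak,
        "cosolvency_height": cfg.cosolvency_height,
        "cosolvency_width": cfg.cosolvency_width,
        "temperature_factor_25_40": cfg.temperature_factor_25_40,
    }
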