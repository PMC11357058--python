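"""Relative sigma-potential descriptors for solubility modelling.

COSMO-RS-style calculations characterise a liquid by its sigma-potential
mu(sigma): the chemical-potential cost of placing a molecular surface
segment of screening charge density sigma into that liquid.  Profiles are
tabulated on a fixed 61-point grid from -0.03 to +0.03 e/A^2 in steps of
0.001.  A solute/solvent pair is described here by the *relative*
potential -- the solute's mu(sigma) minus the mole-fraction-weighted
mu(sigma) of the solvent components -- and informative grid points are
picked by per-point correlation of the descriptor with log-solubility.

The sigma axis splits into three chemically meaningful bands: the
hydrogen-bond-donor band (sigma < -0.01 e/A^2), the non-polar
hydrophobic band (|sigma| <= 0.01), and the hydrogen-bond-acceptor band
(sigma > +0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SIGMA_GRID",
    "N_SIGMA",
    "SigmaGrid",
    "SolventSystem",
    "DescriptorVector",
    "SigmaRegionPartition",
    "GridLookupError",
    "AxisMismatchError",
    "relative_potential",
    "select_features",
    "subset_r2",
    "partition_regions",
    "interpolate_temperature",
    "lookup_grid",
    "read_sigma_tsv",
    "write_sigma_tsv",
    "descriptor_frame",
]

logger = logging.getLogger(__name__)

#: Canonical 61-point sigma axis, e/A^2.
SIGMA_GRID: np.ndarray = np.linspace(-0.03, 0.03, 61)
SIGMA_GRID.setflags(write=False)

N_SIGMA = 61

#: Absolute tolerance for declaring two sigma axes identical.
AXIS_ATOL = 1e-12

#: Grids within this many kelvin of a request are used as-is.
TEMPERATURE_SNAP_K = 0.5


class GridLookupError(KeyError):
    """No sigma-potential grid available for a requested compound/temperature."""


class AxisMismatchError(ValueError):
    """Two grids do not share the canonical sigma axis."""


@dataclass(frozen=True)
class SigmaGrid:
    """A compound's sigma-potential mu(sigma) at one temperature.

    Parameters
    ----------
    compound_id
        Identifier of the pure compound.
    temperature
        Temperature in kelvin.
    sigma_values
        The 61 charge-density points in e/A^2, strictly increasing from
        -0.03 to +0.03 in 0.001 steps.
    mu_values
        The 61 potential values (consistent energy-per-surface units).
    """

    compound_id: str
    temperature: float
    sigma_values: np.ndarray
    mu_values: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma_values, dtype=float)
        mu = np.asarray(self.mu_values, dtype=float)
        if sig.shape != (N_SIGMA,) or mu.shape != (N_SIGMA,):
            raise ValueError(
                f"sigma grid must have exactly {N_SIGMA} points, "
                f"got {sig.shape} / {mu.shape}"
            )
        if not np.all(np.diff(sig) > 0):
            raise ValueError("sigma axis must be strictly increasing")
        if not np.allclose(np.diff(sig), 0.001, atol=AXIS_ATOL, rtol=0.0):
            raise ValueError("sigma axis spacing must be 0.001 e/A^2")
        if not np.all(np.isfinite(mu)):
            raise ValueError("mu values must all be finite")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive kelvin")
        sig.setflags(write=False)
        mu.setflags(write=False)
        object.__setattr__(self, "sigma_values", sig)
        object.__setattr__(self, "mu_values", mu)


@dataclass(frozen=True)
class SolventSystem:
    """A (possibly multicomponent) solvent with solute-free mole fractions.

    ``class_tag`` is one of ``"neat"``, ``"binary"``, ``"DES"``.
    """

    components: tuple[tuple[str, float], ...]
    label: str
    class_tag: str

    def __post_init__(self) -> None:
        comps = tuple((str(c), float(x)) for c, x in self.components)
        ids = [c for c, _ in comps]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate component ids in system {self.label!r}")
        for c, x in comps:
            if not (0.0 < x <= 1.0):
                raise ValueError(
                    f"mole fraction of {c!r} in {self.label!r} is {x}, "
                    "must lie in (0, 1]"
                )
        total = sum(x for _, x in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"mole fractions in {self.label!r} sum to {total}, expected 1"
            )
        if self.class_tag not in ("neat", "binary", "DES"):
            raise ValueError(f"unknown class_tag {self.class_tag!r}")
        object.__setattr__(self, "components", comps)

    @staticmethod
    def neat(compound_id: str, label: str | None = None) -> "SolventSystem":
        return SolventSystem(
            ((compound_id, 1.0),), label or compound_id, "neat"
        )


@dataclass(frozen=True)
class DescriptorVector:
    """Relative solute-solvent sigma-potential for one solubility record."""

    record_id: str
    relative_mu: np.ndarray
    extra: float | None = None
    selected: np.ndarray | None = None

    def __post_init__(self) -> None:
        rel = np.asarray(self.relative_mu, dtype=float)
        if rel.shape != (N_SIGMA,):
            raise ValueError(f"relative_mu must have length {N_SIGMA}")
        if not np.all(np.isfinite(rel)):
            raise ValueError("relative_mu must be finite")
        rel.setflags(write=False)
        object.__setattr__(self, "relative_mu", rel)
        if self.selected is not None:
            sel = np.asarray(self.selected, dtype=bool)
            if sel.shape != (N_SIGMA,):
                raise ValueError("selected mask length must match grid length")
            object.__setattr__(self, "selected", sel)


@dataclass(frozen=True)
class SigmaRegionPartition:
    """Closed partition of the sigma axis into HBD / HYD / HBA bands.

    Defaults put the hydrogen-bond cutoff at |sigma| = 0.01 e/A^2, the
    conventional COSMO-RS threshold: HBD = [-0.03, -0.01), HYD =
    [-0.01, +0.01], HBA = (+0.01, +0.03].
    """

    hbd_max: float = -0.01
    hba_min: float = +0.01

    def __post_init__(self) -> None:
        if not (-0.03 < self.hbd_max <= self.hba_min < 0.03):
            raise ValueError("invalid region cutoffs")

    def region_of(self, sigma: float) -> str:
        if sigma < self.hbd_max:
            return "HBD"
        if sigma > self.hba_min:
            return "HBA"
        return "HYD"

    def region_masks(
        self, sigma_axis: np.ndarray = SIGMA_GRID
    ) -> dict[str, np.ndarray]:
        sig = np.asarray(sigma_axis, dtype=float)
        hbd = sig < self.hbd_max
        hba = sig > self.hba_min
        hyd = ~(hbd | hba)
        return {"HBD": hbd, "HYD": hyd, "HBA": hba}


def _check_axis(grid: SigmaGrid, reference: np.ndarray) -> None:
    if not np.allclose(grid.sigma_values, reference, atol=AXIS_ATOL, rtol=0.0):
        raise AxisMismatchError(
            f"sigma axis of {grid.compound_id!r} at {grid.temperature} K "
            "does not match the canonical axis"
        )


def lookup_grid(
    grids: Iterable[SigmaGrid],
    compound_id: str,
    temperature: float,
    snap_K: float = TEMPERATURE_SNAP_K,
) -> SigmaGrid:
    """Find (or build by interpolation) the grid for a compound at ``temperature``.

    The nearest stored temperature within ``snap_K`` kelvin is used as-is;
    otherwise the two bracketing temperatures are linearly interpolated.

    Raises
    ------
    GridLookupError
        If the compound has no grids, or the temperature is outside the
        stored range by more than ``snap_K``.
    """
    candidates = sorted(
        (g for g in grids if g.compound_id == compound_id),
        key=lambda g: g.temperature,
    )
    if not candidates:
        raise GridLookupError(
            f"no sigma-potential grid available for compound {compound_id!r}"
        )
    temps = np.array([g.temperature for g in candidates])
    nearest = int(np.argmin(np.abs(temps - temperature)))
    if abs(temps[nearest] - temperature) <= snap_K:
        return candidates[nearest]
    below = [g for g in candidates if g.temperature <= temperature]
    above = [g for g in candidates if g.temperature >= temperature]
    if not below or not above:
        raise GridLookupError(
            f"temperature {temperature} K outside the stored range "
            f"[{temps.min()}, {temps.max()}] K for compound {compound_id!r}"
        )
    return interpolate_temperature(below[-1], above[0], temperature)


def relative_potential(
    solute: SigmaGrid,
    system: SolventSystem,
    grids: Iterable[SigmaGrid],
    temperature: float | None = None,
    record_id: str | None = None,
    extra: float | None = None,
) -> DescriptorVector:
    """Relative sigma-potential descriptor of a solute in a solvent system.

    ``relative_mu[i] = mu_solute[i] - sum_k x_k * mu_k[i]`` where ``x_k``
    are the solute-free mole fractions of the solvent components and the
    component potentials are pure-state values at the requested
    temperature.
    """
    if temperature is None:
        temperature = solute.temperature
    grids = list(grids)
    _check_axis(solute, SIGMA_GRID)
    mix = np.zeros(N_SIGMA)
    for comp_id, frac in system.components:
        g = lookup_grid(grids, comp_id, temperature)
        _check_axis(g, solute.sigma_values)
        mix += frac * g.mu_values
    rel = solute.mu_values - mix
    rid = record_id or f"{solute.compound_id}|{system.label}|{temperature:.2f}K"
    return DescriptorVector(record_id=rid, relative_mu=rel, extra=extra)


def _univariate_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of the simple linear regression y ~ x.

    Equals the squared Pearson correlation.  A constant descriptor column
    carries no information and contributes 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def subset_r2(
    descriptors: Sequence[DescriptorVector],
    log_solubility: Sequence[float],
    subset_labels: Sequence[str],
) -> dict[str, np.ndarray]:
    """Per-sigma-index R^2 of log-solubility on relative_mu, per subset.

    Records are split into two subsets: non-DES (``neat`` + ``binary``
    class tags) and DES.  Returns a mapping ``{"non-DES": r2[61],
    "DES": r2[61]}``; subsets absent from the data map to zeros.
    """
    X = np.vstack([d.relative_mu for d in descriptors])
    y = np.asarray(list(log_solubility), dtype=float)
    if X.shape[0] != y.shape[0] or len(subset_labels) != y.shape[0]:
        raise ValueError("descriptors, responses and labels must align")
    tags = np.asarray(
        ["DES" if t == "DES" else "non-DES" for t in subset_labels]
    )
    out: dict[str, np.ndarray] = {}
    for name in ("non-DES", "DES"):
        idx = tags == name
        r2 = np.zeros(N_SIGMA)
        if idx.sum() >= 3:
            for j in range(N_SIGMA):
                col = X[idx, j]
                if np.ptp(col) == 0.0:
                    logger.warning(
                        "constant descriptor column at sigma index %d in "
                        "subset %s; R^2 set to 0", j, name,
                    )
                    continue
                r2[j] = _univariate_r2(col, y[idx])
        out[name] = r2
    return out


def select_features(
    descriptors: Sequence[DescriptorVector],
    log_solubility: Sequence[float],
    subset_labels: Sequence[str],
    threshold: float = 0.4,
) -> np.ndarray:
    """Boolean mask over the 61 sigma points worth keeping as descriptors.

    A grid point is selected when the squared correlation of a univariate
    linear fit of log10 solubility on the relative potential exceeds
    ``threshold`` in the non-DES subset, the DES subset, or both.
    """
    r2 = subset_r2(descriptors, log_solubility, subset_labels)
    mask = (r2["non-DES"] > threshold) | (r2["DES"] > threshold)
    return mask


def partition_regions(
    partition: SigmaRegionPartition,
    mask: np.ndarray,
    sigma_axis: np.ndarray = SIGMA_GRID,
) -> dict[str, list[int]]:
    """Assign each selected sigma index to its HBD / HYD / HBA band."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(sigma_axis).shape:
        raise ValueError("mask length must match the sigma axis")
    out: dict[str, list[int]] = {"HBD": [], "HYD": [], "HBA": []}
    for i in np.flatnonzero(mask):
        out[partition.region_of(float(sigma_axis[i]))].append(int(i))
    return out


def interpolate_temperature(
    grid_low: SigmaGrid,
    grid_high: SigmaGrid,
    temperature: float,
    allow_extrapolation: bool = False,
) -> SigmaGrid:
    """Pointwise linear interpolation of mu(sigma) in temperature.

    Endpoint requests reproduce the stored grids exactly.
    """
    if grid_low.compound_id != grid_high.compound_id:
        raise ValueError("grids belong to different compounds")
    _check_axis(grid_high, grid_low.sigma_values)
    t0, t1 = grid_low.temperature, grid_high.temperature
    if t1 < t0:
        grid_low, grid_high = grid_high, grid_low
        t0, t1 = t1, t0
    if temperature == t0:
        return grid_low
    if temperature == t1:
        return grid_high
    if not (t0 <= temperature <= t1) and not allow_extrapolation:
        raise ValueError(
            f"temperature {temperature} K outside [{t0}, {t1}] K; "
            "pass allow_extrapolation=True to override"
        )
    if t1 == t0:
        return grid_low
    w = (temperature - t0) / (t1 - t0)
    mu = (1.0 - w) * grid_low.mu_values + w * grid_high.mu_values
    return SigmaGrid(
        compound_id=grid_low.compound_id,
        temperature=float(temperature),
        sigma_values=grid_low.sigma_values,
        mu_values=mu,
    )


# ---------------------------------------------------------------------------
# I/O

def write_sigma_tsv(grid: SigmaGrid, path) -> None:
    """Write a sigma-potential table: '#' header lines, then sigma/mu columns."""
    with open(path, "w") as fh:
        fh.write(f"# compound_id: {grid.compound_id}\n")
        fh.write(f"# temperature_K: {grid.temperature}\n")
        fh.write("# sigma_e_per_A2\tmu\n")
        for s, m in zip(grid.sigma_values, grid.mu_values):
            fh.write(f"{s:.3f}\t{m:.12g}\n")


def read_sigma_tsv(path) -> SigmaGrid:
    """Read a sigma-potential table written by :func:`write_sigma_tsv`."""
    compound_id = None
    temperature = None
    sigmas: list[float] = []
    mus: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("compound_id:"):
                    compound_id = body.split(":", 1)[1].strip()
                elif body.startswith("temperature_K:"):
                    temperature = float(body.split(":", 1)[1])
                continue
            s, m = line.split("\t")
            sigmas.append(float(s))
            mus.append(float(m))
    if compound_id is None or temperature is None:
        raise ValueError(f"missing compound_id/temperature headers in {path}")
    return SigmaGrid(
        compound_id=compound_id,
        temperature=temperature,
        sigma_values=np.array(sigmas),
        mu_values=np.array(mus),
    )


def descriptor_frame(descriptors: Sequence[DescriptorVector]):
    """Descriptor matrix as a pandas DataFrame.

    Columns are ``mu_rel_<sigma>`` for the 61 grid points plus an optional
    ``x_cosmo`` column when any record carries the computed-solubility
    extra descriptor.
    """
    import pandas as pd

    cols = [f"mu_rel_{s:+.3f}" for s in SIGMA_GRID]
    data = np.vstack([d.relative_mu for d in descriptors])
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "record_id", [d.record_id for d in descriptors])
    if any(d.extra is not None for d in descriptors):
        df["x_cosmo"] = [
            d.extra if d.extra is not None else np.nan for d in descriptors
        ]
    return df
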