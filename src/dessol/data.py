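"""Solubility dataset assembly, validation and summaries.

The modelling dataset mixes newly measured deep-eutectic-solvent (DES)
records with literature values for neat solvents and one binary aqueous
mixture.  This module holds the record and manifest containers, the
enumeration of the experimental DES design (2 hydrogen-bond acceptors x
6 polyol donors x 3 molar ratios = 36 systems), validation/summary
logic, solvent rankings, and CSV round-tripping.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd

from .sigma import SolventSystem

__all__ = [
    "HBA_IDS",
    "HBD_IDS",
    "MOLAR_RATIOS",
    "STUDY_TEMPERATURES_K",
    "SolubilityRecord",
    "DatasetManifest",
    "DesignSpec",
    "ValidationError",
    "make_record_id",
    "enumerate_design",
    "des_system",
    "aqueous_des_system",
    "validate_and_summarize",
    "rank_systems",
    "records_to_frame",
    "frame_to_records",
    "write_records_csv",
    "read_records_csv",
]

logger = logging.getLogger(__name__)

#: Hydrogen-bond acceptors: choline chloride, betaine.
HBA_IDS = ("ChCl", "BI")
#: Hydrogen-bond donors: six polyols.
HBD_IDS = ("ETG", "DEG", "TEG", "GLY", "P2D", "B3D")
#: HBA:HBD molar ratios 1:n.
MOLAR_RATIOS = (1, 2, 4)
#: Measurement temperatures, K (25, 30, 35, 40 deg C).
STUDY_TEMPERATURES_K = (298.15, 303.15, 308.15, 313.15)


class ValidationError(ValueError):
    """A record collection failed validation; carries the per-record report."""

    def __init__(self, report: list[str]):
        super().__init__(
            "dataset validation failed:\n" + "\n".join(report)
        )
        self.report = report


@dataclass(frozen=True)
class SolubilityRecord:
    """One saturation measurement of a solute in a solvent system."""

    record_id: str
    solute_id: str
    system: SolventSystem
    temperature: float
    x_solubility: float
    source: str = "this_work"  # {"this_work", "literature"}
    class_tag: str = "DES"

    def validate(self) -> list[str]:
        problems = []
        if not (0.0 < self.x_solubility < 1.0):
            problems.append(
                f"{self.record_id}: x_solubility {self.x_solubility} "
                "outside (0, 1)"
            )
        if not (273.0 <= self.temperature <= 373.0):
            problems.append(
                f"{self.record_id}: temperature {self.temperature} K outside "
                "the study scope [273, 373]"
            )
        if self.source not in ("this_work", "literature"):
            problems.append(f"{self.record_id}: unknown source {self.source!r}")
        if self.class_tag not in ("neat", "binary", "DES"):
            problems.append(
                f"{self.record_id}: unknown class_tag {self.class_tag!r}"
            )
        return problems


@dataclass(frozen=True)
class DatasetManifest:
    """Counts by provenance class and distinct system."""

    n_total: int
    n_neat: int
    n_binary: int
    n_des: int
    n_neat_systems: int
    n_binary_systems: int
    n_des_systems: int = 0
    duplicates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_total != self.n_neat + self.n_binary + self.n_des:
            raise ValueError("manifest totals inconsistent")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class DesignSpec:
    """The experimental DES design grid."""

    hba_list: tuple[str, ...] = HBA_IDS
    hbd_list: tuple[str, ...] = HBD_IDS
    molar_ratios: tuple[int, ...] = MOLAR_RATIOS
    selected_aqueous_systems: tuple[tuple[str, str, int], ...] = (
        ("ChCl", "TEG", 2),
        ("ChCl", "DEG", 2),
        ("BI", "TEG", 2),
        ("BI", "GLY", 2),
    )
    temperatures: tuple[float, ...] = STUDY_TEMPERATURES_K

    def __post_init__(self) -> None:
        if not (self.hba_list and self.hbd_list and self.molar_ratios):
            raise ValueError("design lists must be nonempty")
        for n in self.molar_ratios:
            if n < 1:
                raise ValueError("HBD multiplier must be >= 1")


def make_record_id(
    solute_id: str, system_label: str, temperature: float, source: str
) -> str:
    """Deterministic record id: short hash of (solute, system, T, source)."""
    key = f"{solute_id}|{system_label}|{temperature:.4f}|{source}"
    return hashlib.sha1(key.encode()).hexdigest()[:12]


def des_system(hba: str, hbd: str, ratio_n: int) -> SolventSystem:
    """A neat DES at HBA:HBD = 1:n, expressed as component mole fractions."""
    n = int(ratio_n)
    return SolventSystem(
        components=((hba, 1.0 / (1 + n)), (hbd, n / (1.0 + n))),
        label=f"{hba}-{hbd} 1:{n}",
        class_tag="DES",
    )


def aqueous_des_system(
    hba: str, hbd: str, ratio_n: int, x_star_des: float
) -> SolventSystem:
    """A DES-water ternary at solute-free DES mole fraction ``x_star_des``.

    The DES is expanded to its elementary components: water gets
    1 - x*, the HBA x*/(1+n) and the HBD x*.n/(1+n), so the
    mole-fraction weighting of pure-component sigma-potentials applies
    unchanged.  ``x_star_des = 1`` returns the neat DES.
    """
    if not (0.0 < x_star_des <= 1.0):
        raise ValueError("x_star_des must lie in (0, 1]")
    n = int(ratio_n)
    if x_star_des == 1.0:
        return des_system(hba, hbd, n)
    comps = (
        ("water", 1.0 - x_star_des),
        (hba, x_star_des / (1 + n)),
        (hbd, x_star_des * n / (1.0 + n)),
    )
    return SolventSystem(
        components=comps,
        label=f"{hba}-{hbd} 1:{n} + water (x*={x_star_des:g})",
        class_tag="DES",
    )


def enumerate_design(spec: DesignSpec | None = None) -> list[SolventSystem]:
    """All neat DES systems of the design grid, in (HBA, HBD, ratio) order."""
    spec = spec or DesignSpec()
    return [
        des_system(hba, hbd, n)
        for hba in spec.hba_list
        for hbd in spec.hbd_list
        for n in spec.molar_ratios
    ]


def validate_and_summarize(
    records: Iterable[SolubilityRecord],
) -> DatasetManifest:
    """Validate every record and summarise counts by class and system.

    Duplicate (system label, temperature) pairs are flagged in the
    manifest but both copies are counted.  Any fatal invariant violation
    aborts with a :class:`ValidationError` carrying the full report.
    """
    records = list(records)
    report: list[str] = []
    for r in records:
        report.extend(r.validate())
    if report:
        raise ValidationError(report)

    by_class = {"neat": 0, "binary": 0, "DES": 0}
    # a "system" is the solvent combination; compositions within a
    # mixture are points of the same system
    systems: dict[str, set] = {"neat": set(), "binary": set(), "DES": set()}
    seen: dict[tuple[str, float], int] = {}
    duplicates: list[str] = []
    for r in records:
        by_class[r.class_tag] += 1
        if r.class_tag == "DES":
            # DES identity includes the molar ratio; aqueous dilutions
            # of a DES belong to its base formulation
            systems["DES"].add(r.system.label.split(" + water")[0])
        else:
            systems[r.class_tag].add(
                frozenset(c for c, _ in r.system.components)
            )
        key = (r.system.label, round(r.temperature, 4))
        seen[key] = seen.get(key, 0) + 1
        if seen[key] == 2:
            duplicates.append(f"{key[0]} @ {key[1]} K")
    if duplicates:
        logger.warning("duplicate (system, T) pairs: %s", duplicates)
    return DatasetManifest(
        n_total=len(records),
        n_neat=by_class["neat"],
        n_binary=by_class["binary"],
        n_des=by_class["DES"],
        n_neat_systems=len(systems["neat"]),
        n_binary_systems=len(systems["binary"]),
        n_des_systems=len(systems["DES"]),
        duplicates=tuple(duplicates),
    )


def rank_systems(
    records: Iterable[SolubilityRecord],
    hba: str,
    temperature: float,
    ratio_n: int,
    hbd_ids: Sequence[str] = HBD_IDS,
    temp_atol: float = 0.01,
) -> list[str]:
    """Rank hydrogen-bond donors by descending solubility for one HBA/ratio.

    Expects exactly one record per HBD after filtering to the requested
    HBA, molar ratio and temperature.  Ties break alphabetically with a
    warning.
    """
    wanted_labels = {
        f"{hba}-{hbd} 1:{int(ratio_n)}": hbd for hbd in hbd_ids
    }
    found: dict[str, float] = {}
    for r in records:
        hbd = wanted_labels.get(r.system.label)
        if hbd is not None and abs(r.temperature - temperature) <= temp_atol:
            found[hbd] = r.x_solubility
    missing = [h for h in hbd_ids if h not in found]
    if missing:
        raise KeyError(
            f"no record for HBDs {missing} with {hba} 1:{ratio_n} "
            f"at {temperature} K"
        )
    values = sorted(found.values())
    if len(set(values)) != len(values):
        logger.warning("solubility ties in ranking; breaking alphabetically")
    return sorted(found, key=lambda h: (-found[h], h))


# ---------------------------------------------------------------------------
# CSV round-trip

_CSV_COLUMNS = [
    "record_id", "solute", "system_label", "component_ids",
    "component_fracs", "T_K", "x_solubility", "class_tag", "source",
]


def records_to_frame(records: Iterable[SolubilityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "solute": r.solute_id,
            "system_label": r.system.label,
            "component_ids": ";".join(c for c, _ in r.system.components),
            "component_fracs": ";".join(
                repr(x) for _, x in r.system.components
            ),
            "T_K": r.temperature,
            "x_solubility": r.x_solubility,
            "class_tag": r.class_tag,
            "source": r.source,
        })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SolubilityRecord]:
    out = []
    for row in df.itertuples(index=False):
        comps = tuple(
            zip(
                str(row.component_ids).split(";"),
                (float(x) for x in str(row.component_fracs).split(";")),
            )
        )
        system = SolventSystem(
            components=comps, label=str(row.system_label),
            class_tag=str(row.class_tag),
        )
        out.append(SolubilityRecord(
            record_id=str(row.record_id),
            solute_id=str(row.solute),
            system=system,
            temperature=float(row.T_K),
            x_solubility=float(row.x_solubility),
            source=str(row.source),
            class_tag=str(row.class_tag),
        ))
    return out


def write_records_csv(records: Iterable[SolubilityRecord], path) -> None:
    # %.17g round-trips IEEE doubles exactly
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path) -> list[SolubilityRecord]:
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))
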