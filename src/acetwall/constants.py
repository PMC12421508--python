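"""Physical constants and unit conventions.

Internal units are Å for length, ns for time, g/mol for mass and
kcal/mol for energy.  Diffusion coefficients convert to the customary
cm²/s scale via ``1 Å²/ns = 1e-7 cm²/s``.
"""

from __future__ import annotations

from dataclasses import dataclass

#: gas constant, kcal mol^-1 K^-1
R_KCAL = 1.987204e-3
#: Avogadro's number, mol^-1
AVOGADRO = 6.02214e23
#: molecular weight of water, g/mol
MW_H2O = 18.02
#: exact unit conversion Å²/ns -> cm²/s
A2_PER_NS_TO_CM2_PER_S = 1e-7
#: 1 Å³ in cm³
A3_TO_CM3 = 1e-24

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "NA": 22.990,
    "FE": 55.845,
}

#: heavy atoms that make up one instance of each functional group
#: (hydroxyl: O; carboxyl: C + 2 O; acetyl: carbonyl C, carbonyl O,
#: ester O, methyl C)
HEAVY_ATOMS_PER_GROUP = {"hydroxyl": 1, "carboxyl": 3, "acetyl": 4}

#: mass of an acetyl substituent C(=O)CH3, g/mol
ACETYL_MASS = 2 * ATOMIC_MASSES["C"] + 3 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]
#: net mass change per acetylated hydroxyl (acetyl added, hydroxyl H removed)
ACETYLATION_MASS_DELTA = ACETYL_MASS - ATOMIC_MASSES["H"]
#: net atom-count change per acetylated hydroxyl (+6 added, 1 H removed)
ACETYLATION_ATOM_DELTA = 5
#: atoms per water molecule
ATOMS_PER_WATER = 3


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants bundle used throughout the analyses.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K (default 300, the simulation thermostat
        set point).
    rho_water : float
        Water density in g/cm³ used by the constant-volume water-removal
        bookkeeping (default 0.997 at 300 K; configurable).
    """

    temperature: float = 300.0
    rho_water: float = 0.997
    gas_constant: float = R_KCAL
    mw_water: float = MW_H2O
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.rho_water <= 0:
            raise ValueError("water density must be positive")

    @property
    def kT(self) -> float:
        """R·T in kcal/mol (thermal energy per mole)."""
        return self.gas_constant * self.temperature


DEFAULT_CONSTANTS = Constants()
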