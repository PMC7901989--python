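"""Acetogenic reaction stoichiometry and the electron-equivalents ledger.

Homoacetogens growing on ethanol couple ethanol oxidation to acetate
(releasing H2) with CO2 reduction to acetate via the Wood-Ljungdahl pathway:

    2 CH3CH2OH + 2 H2O  -> 2 CH3COOH + 4 H2        (ethanol oxidation)
    4 H2 + 2 CO2        -> CH3COOH + 2 H2O         (CO2 reduction)
    -------------------------------------------------------------
    2 CH3CH2OH + 2 CO2  -> 3 CH3COOH               (overall)

so one mol of ethanol yields 1.5 mol acetate when every electron ends up in
acetate.  The ledger tracks electron equivalents: ethanol oxidation releases
4 e-/mol, acetate synthesis from CO2 sinks 8 e-/mol (4 H2 x 2 e-), H2 carries
2 e-/mol, and Fe(III) -> Fe(II) sinks 1 e-/mol.  An acetate deficit of a
mineral-amended culture relative to its mineral-free control therefore
corresponds to 8x that many electron equivalents diverted away from
acetogenesis, and the fraction of those electrons recovered as Fe(II) is the
diversion efficiency of mineral reduction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, NamedTuple

import yaml

__all__ = [
    "Reaction",
    "ElectronLedger",
    "LEDGER",
    "MineralSpec",
    "MINERALS",
    "load_minerals",
    "theoretical_acetate",
    "electron_equivalents",
    "acetate_deficit_electrons",
    "DeficitResult",
    "diversion_efficiency",
    "headspace_gas_moles",
    "mineral_loading_for_fe",
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE_K",
]

#: J mol^-1 K^-1
GAS_CONSTANT = 8.314

#: Cultivation temperature (30 degC); exposed as a parameter on gas-phase math.
DEFAULT_TEMPERATURE_K = 303.15

#: Elemental composition of the species appearing in the acetogenic reactions.
_COMPOSITION: Mapping[str, Mapping[str, int]] = {
    "ethanol": {"C": 2, "H": 6, "O": 1},
    "water": {"H": 2, "O": 1},
    "acetate": {"C": 2, "H": 4, "O": 2},
    "H2": {"H": 2},
    "CO2": {"C": 1, "O": 2},
}


@dataclasses.dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction over the species in ``_COMPOSITION``."""

    name: str
    reactants: Mapping[str, float]
    products: Mapping[str, float]

    def net(self) -> dict[str, float]:
        """Products minus reactants, as signed coefficients per species."""
        net: dict[str, float] = {}
        for sp, c in self.reactants.items():
            net[sp] = net.get(sp, 0.0) - c
        for sp, c in self.products.items():
            net[sp] = net.get(sp, 0.0) + c
        return {sp: c for sp, c in net.items() if c != 0}

    def element_balance(self) -> dict[str, float]:
        balance: dict[str, float] = {}
        for sp, coeff in self.net().items():
            for element, count in _COMPOSITION[sp].items():
                balance[element] = balance.get(element, 0.0) + coeff * count
        return balance

    def is_balanced(self) -> bool:
        return all(abs(v) < 1e-12 for v in self.element_balance().values())


ETHANOL_OXIDATION = Reaction(
    "ethanol_oxidation", {"ethanol": 2, "water": 2}, {"acetate": 2, "H2": 4}
)
CO2_REDUCTION = Reaction("co2_reduction", {"H2": 4, "CO2": 2}, {"acetate": 1, "water": 2})
OVERALL = Reaction("overall", {"ethanol": 2, "CO2": 2}, {"acetate": 3})

#: Electron equivalents per mole for each ledger entry.
ELECTRON_EQUIV = {"ethanol_ox": 4.0, "acetate_synth": 8.0, "H2": 2.0, "Fe": 1.0}


@dataclasses.dataclass(frozen=True)
class ElectronLedger:
    """The three acetogenic reactions plus per-species electron equivalents.

    Construction verifies that each reaction is element-balanced and that the
    overall reaction is the exact sum of the two half-processes.
    """

    ethanol_oxidation: Reaction = ETHANOL_OXIDATION
    co2_reduction: Reaction = CO2_REDUCTION
    overall: Reaction = OVERALL
    electron_equiv: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(ELECTRON_EQUIV)
    )

    def __post_init__(self) -> None:
        for rxn in (self.ethanol_oxidation, self.co2_reduction, self.overall):
            if not rxn.is_balanced():
                raise ValueError(f"reaction {rxn.name!r} is not element-balanced")
        combined: dict[str, float] = {}
        for rxn in (self.ethanol_oxidation, self.co2_reduction):
            for sp, c in rxn.net().items():
                combined[sp] = combined.get(sp, 0.0) + c
        combined = {sp: c for sp, c in combined.items() if abs(c) > 1e-12}
        if combined != self.overall.net():
            raise ValueError("overall reaction is not the sum of the half-processes")
        # 4 H2 per acetate in CO2 reduction <=> 8 e- per acetate
        h2 = self.co2_reduction.reactants["H2"]
        ac = self.co2_reduction.products["acetate"]
        if self.electron_equiv["acetate_synth"] != h2 / ac * self.electron_equiv["H2"]:
            raise ValueError("acetate electron sink inconsistent with H2 stoichiometry")


#: Validated module-level ledger instance.
LEDGER = ElectronLedger()


@dataclasses.dataclass(frozen=True)
class MineralSpec:
    """An iron mineral and its Fe(III)/Fe(II) content per formula unit."""

    name: str
    formula: str
    fe3_per_formula_unit: int
    fe2_per_formula_unit: int = 0

    def __post_init__(self) -> None:
        if self.fe3_per_formula_unit < 0 or self.fe2_per_formula_unit < 0:
            raise ValueError("iron counts per formula unit must be >= 0")


MINERALS: dict[str, MineralSpec] = {
    "HFO": MineralSpec("HFO", "Fe(OH)3", 1),
    "goethite": MineralSpec("goethite", "FeO(OH)", 1),
    "hematite": MineralSpec("hematite", "Fe2O3", 2),
    "magnetite": MineralSpec("magnetite", "Fe3O4", 2, 1),
    "Fe-NTA": MineralSpec("Fe-NTA", "FeC6H6NO6", 1),
}


def load_minerals(path: str | Path) -> dict[str, MineralSpec]:
    """Load a user mineral table (YAML mapping name -> {formula, fe3, fe2})."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table: dict[str, MineralSpec] = {}
    for name, entry in raw.items():
        table[name] = MineralSpec(
            name=name,
            formula=str(entry.get("formula", "")),
            fe3_per_formula_unit=int(entry.get("fe3", 0)),
            fe2_per_formula_unit=int(entry.get("fe2", 0)),
        )
    return table


def theoretical_acetate(ethanol_consumed: float) -> float:
    """Acetate expected from complete acetogenic conversion of ethanol.

    The overall reaction converts 2 ethanol to 3 acetate, i.e. 1.5 mol acetate
    per mol ethanol.  Input and output share the same unit prefix.
    """
    if ethanol_consumed < 0:
        raise ValueError("ethanol_consumed must be >= 0")
    ratio = OVERALL.products["acetate"] / OVERALL.reactants["ethanol"]
    return ratio * ethanol_consumed


def electron_equivalents(species: str, amount: float) -> float:
    """Electron equivalents carried/sunk by ``amount`` of a ledger species.

    ``species`` is one of ``ethanol_ox`` (4 e-/mol released), ``acetate_synth``
    (8 e-/mol sunk), ``H2`` (2 e-/mol), ``Fe`` (1 e-/mol).  The unit prefix of
    the input (µmol, mmol, ...) is preserved.
    """
    if species not in ELECTRON_EQUIV:
        raise KeyError(f"unknown ledger species {species!r}; expected one of {sorted(ELECTRON_EQUIV)}")
    if amount < 0:
        raise ValueError("amount must be >= 0")
    return ELECTRON_EQUIV[species] * amount


class DeficitResult(NamedTuple):
    electrons: float
    clamped: bool


def acetate_deficit_electrons(control_acetate: float, treatment_acetate: float) -> DeficitResult:
    """Electrons diverted from acetogenesis, from an acetate deficit.

    A mineral-amended culture producing less acetate than its mineral-free
    control has diverted 8 electron equivalents per missing acetate.  Negative
    deficits (treatment above control, which replicate noise can produce for
    the small deficits involved) are clamped to zero and flagged rather than
    raised.
    """
    if control_acetate < 0 or treatment_acetate < 0:
        raise ValueError("acetate amounts must be >= 0")
    deficit = control_acetate - treatment_acetate
    if deficit < 0:
        return DeficitResult(0.0, True)
    return DeficitResult(ELECTRON_EQUIV["acetate_synth"] * deficit, False)


def diversion_efficiency(fe2_electrons: float, diverted_electrons: float) -> float:
    """Fraction of diverted electrons recovered as Fe(II) (1 e- per Fe)."""
    if fe2_electrons < 0:
        raise ValueError("fe2_electrons must be >= 0")
    if diverted_electrons <= 0:
        raise ZeroDivisionError("diversion efficiency undefined for zero diverted electrons")
    return fe2_electrons / diverted_electrons


def headspace_gas_moles(
    partial_pressure_kPa: float,
    headspace_volume_mL: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Ideal-gas amount (mmol) of a headspace component.

    n = PV/RT; with P in kPa and V in mL the result is directly in mmol.
    Default temperature is the 30 degC cultivation temperature.
    """
    if partial_pressure_kPa <= 0 or headspace_volume_mL <= 0 or temperature_K <= 0:
        raise ValueError("pressure, volume and temperature must be > 0")
    return partial_pressure_kPa * headspace_volume_mL / (GAS_CONSTANT * temperature_K)


def mineral_loading_for_fe(mineral: MineralSpec, target_fe3_mM: float) -> float:
    """Mineral loading (mmol/L) delivering a target Fe(III) concentration.

    Crystalline oxides are dosed to match the Fe(III) atom count of a 9 mM HFO
    amendment: hematite (2 Fe(III)/unit) needs 4.5 mmol/L, goethite 9 mmol/L.
    """
    if target_fe3_mM < 0:
        raise ValueError("target_fe3_mM must be >= 0")
    if mineral.fe3_per_formula_unit <= 0:
        raise ValueError(f"mineral {mineral.name!r} carries no Fe(III)")
    return target_fe3_mM / mineral.fe3_per_formula_unit
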