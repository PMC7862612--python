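"""Equilibrium-partitioning prediction of baseline (narcosis) cytotoxicity.

Baseline toxicants act by non-specific intercalation into membrane lipids;
a critical membrane concentration of ~69 mmol per litre of membrane lipid
produces 10% cytotoxicity regardless of the chemical. Given a chemical's
lipid-water and protein-water distribution ratios at pH 7.4 (D_lipw,
D_protw) and its air-water partition ratio (K_aw), a mass balance over the
assay compartments (aqueous medium, medium and cell protein, medium and
cell lipid, headspace) converts that membrane concentration into the
nominal medium concentration IC10_baseline expected to produce 10%
cytotoxicity. Chemicals whose equilibrium headspace fraction exceeds a
threshold (default 10%) are flagged volatile and excluded downstream, the
way a ~90%-evaporating chemical must be.

Nominal concentration is defined on the liquid dose volume (water +
protein + lipid); the headspace contributes capacity but not dose volume.
Distribution ratios are consumed as given; no ionisation correction or
plastic-sorption term is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: critical membrane concentration triggering 10% cytotoxicity, mmol/L lipid
CRITICAL_MEMBRANE_CONC_MM = 69.0

VOLATILITY_THRESHOLD = 0.10


@dataclass(frozen=True)
class ChemicalProfile:
    """Partitioning properties of one test chemical at pH 7.4."""

    name: str
    d_lipw: float     # lipid-water distribution ratio (volume basis)
    d_protw: float    # protein-water distribution ratio
    k_aw: float = 0.0  # air-water partition ratio
    concentrations_um: tuple[float, ...] = ()

    def __post_init__(self):
        if self.d_lipw <= 0:
            raise ValueError("d_lipw must be > 0")
        if self.d_protw < 0 or self.k_aw < 0:
            raise ValueError("d_protw and k_aw must be >= 0")


@dataclass(frozen=True)
class CompartmentSystem:
    """Volumes of the in vitro assay compartments (consistent units).

    The defaults are a documented stub for a ~200 uL microplate well with
    0.5% FBS-supplemented medium and a small leukocyte pellet; real
    analyses should supply measured volumes.
    """

    v_water: float = 2.0e-4          # L, aqueous medium
    v_protein_medium: float = 3.2e-9  # L, FBS protein
    v_lipid_medium: float = 4.0e-10   # L, FBS lipid
    v_protein_cell: float = 6.0e-11   # L
    v_lipid_cell: float = 2.0e-11     # L
    v_air: float = 1.0e-4             # L headspace
    c_mem_crit_mm: float = CRITICAL_MEMBRANE_CONC_MM

    def __post_init__(self):
        vols = (self.v_water, self.v_protein_medium, self.v_lipid_medium,
                self.v_protein_cell, self.v_lipid_cell, self.v_air)
        if any(v < 0 for v in vols):
            raise ValueError("volumes must be >= 0")
        if self.v_water <= 0:
            raise ValueError("v_water must be > 0")
        if self.c_mem_crit_mm <= 0:
            raise ValueError("critical membrane concentration must be > 0")

    @property
    def v_protein_total(self) -> float:
        return self.v_protein_medium + self.v_protein_cell

    @property
    def v_lipid_total(self) -> float:
        return self.v_lipid_medium + self.v_lipid_cell

    @property
    def v_medium_total(self) -> float:
        """Liquid dose volume on which nominal concentration is defined."""
        return self.v_water + self.v_protein_total + self.v_lipid_total


@dataclass(frozen=True)
class BaselinePrediction:
    """Predicted nominal IC10_baseline and the equilibrium distribution."""

    chemical: str
    ic10_um: float
    fractions: dict[str, float] = field(default_factory=dict)
    air_loss_fraction: float = 0.0
    volatile: bool = False


def _capacities(chem: ChemicalProfile, sys: CompartmentSystem
                ) -> dict[str, float]:
    """Equilibrium capacity (partition ratio x volume) per compartment."""
    return {
        "water": sys.v_water,
        "protein": chem.d_protw * sys.v_protein_total,
        "lipid": chem.d_lipw * sys.v_lipid_total,
        "air": chem.k_aw * sys.v_air,
    }


def equilibrium_fractions(chem: ChemicalProfile,
                          sys: CompartmentSystem) -> dict[str, float]:
    """Mass fraction of the chemical in each compartment at equilibrium.

    With free aqueous concentration C_w, compartment masses are
    C_w * V_water, D_protw * C_w * V_prot, D_lipw * C_w * V_lip and
    K_aw * C_w * V_air; fractions are these normalised to the total and
    sum to 1.
    """
    caps = _capacities(chem, sys)
    total = sum(caps.values())
    if total <= 0:
        raise ValueError("all compartment capacities are zero")
    return {k: v / total for k, v in caps.items()}


def air_loss_fraction(chem: ChemicalProfile, sys: CompartmentSystem,
                      threshold: float = VOLATILITY_THRESHOLD
                      ) -> tuple[float, bool]:
    """Equilibrium headspace fraction and the volatile-exclusion flag."""
    frac = equilibrium_fractions(chem, sys)["air"]
    return frac, frac > threshold


def predict_ic10(chem: ChemicalProfile, sys: CompartmentSystem,
                 volatility_threshold: float = VOLATILITY_THRESHOLD
                 ) -> BaselinePrediction:
    """Nominal IC10_baseline: the dose at which membrane lipid reaches the
    critical concentration.

    At equilibrium the lipid-phase concentration is D_lipw * C_w; setting
    it to the critical membrane concentration gives
    C_w = C_crit / D_lipw, total mass C_w * (sum of capacities), and
    nominal concentration mass / V_medium_total. The critical membrane
    concentration in mmol/L converts to a nominal value in uM (x1000).
    """
    caps = _capacities(chem, sys)
    c_w_mm = sys.c_mem_crit_mm / chem.d_lipw
    total_mass = c_w_mm * sum(caps.values())      # mmol (per L units)
    ic10_mm = total_mass / sys.v_medium_total
    frac, volatile = air_loss_fraction(chem, sys, volatility_threshold)
    return BaselinePrediction(chemical=chem.name,
                              ic10_um=float(ic10_mm * 1000.0),
                              fractions=equilibrium_fractions(chem, sys),
                              air_loss_fraction=float(frac),
                              volatile=volatile)


def lipid_concentration_at(nominal_um: float, chem: ChemicalProfile,
                           sys: CompartmentSystem) -> float:
    """Lipid-phase concentration (mmol/L lipid) at a nominal dose (uM).

    Forward check for the IC10 inversion: at the predicted IC10 this
    returns the critical membrane concentration.
    """
    caps = _capacities(chem, sys)
    total_mass_mm = nominal_um / 1000.0 * sys.v_medium_total
    c_w_mm = total_mass_mm / sum(caps.values())
    return float(chem.d_lipw * c_w_mm)


def partition_report(chems: list[ChemicalProfile], sys: CompartmentSystem
                     ):
    """Prediction table: one row per chemical (IC10 uM, fractions, flag)."""
    import pandas as pd

    rows = []
    for chem in chems:
        pred = predict_ic10(chem, sys)
        rows.append({"chemical": chem.name, "ic10_um": pred.ic10_um,
                     **{f"fraction_{k}": v for k, v in pred.fractions.items()},
                     "air_loss_fraction": pred.air_loss_fraction,
                     "volatile": pred.volatile})
    return pd.DataFrame(rows)
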