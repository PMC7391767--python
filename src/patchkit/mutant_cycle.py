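"""Thermodynamic double-mutant-cycle coupling energetics.

A four-corner perturbation design — wild type vs point mutant crossed
with a ligand vs a chemically modified analog — tests whether the
mutated residue and the modified chemical group interact.  If their
contributions to binding were additive, the fold-changes in dissociation
constant would cancel around the cycle and

    LnΩ = Ln( Kd_1 · Kd_4 / (Kd_2 · Kd_3) )

would be zero (Kd_1: WT/ligand, Kd_2: mutant/ligand, Kd_3: WT/analog,
Kd_4: mutant/analog).  A nonzero LnΩ quantifies non-additivity; the
coupling energy is |LnΩ|·kT.  Couplings above 1.5 kT (≈0.89 kcal/mol at
24 °C) are conventionally taken as evidence of a specific, short-range
(< 4 Å) interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants as _const

__all__ = [
    "CyclePair",
    "CouplingResult",
    "ln_omega",
    "coupling_energy",
    "classify_specific",
    "DEFAULT_TEMPERATURE_K",
    "SPECIFICITY_THRESHOLD_KT",
]

DEFAULT_TEMPERATURE_K = 297.15  # 24 °C, the conventional conversion temperature
SPECIFICITY_THRESHOLD_KT = 1.5
_J_PER_KCAL = 4184.0  # thermochemical calorie


@dataclass
class CyclePair:
    """The four Kd values of one mutant cycle, all in the same units."""

    kd_wt_ligand: float  # Kd_1
    kd_mut_ligand: float  # Kd_2
    kd_wt_analog: float  # Kd_3
    kd_mut_analog: float  # Kd_4
    mutant: str = ""
    ligand: str = ""
    analog: str = ""

    def __post_init__(self) -> None:
        for v in (self.kd_wt_ligand, self.kd_mut_ligand,
                  self.kd_wt_analog, self.kd_mut_analog):
            if not (np.isfinite(v) and v > 0):
                raise ValueError("all four Kd values must be positive and finite")


@dataclass
class CouplingResult:
    ln_omega: float  # signed
    energy_kT: float  # |LnΩ|
    energy_kcal_mol: float
    temperature: float  # K
    is_specific: bool
    threshold_kT: float = SPECIFICITY_THRESHOLD_KT


def ln_omega(cycle: CyclePair) -> float:
    """Signed non-additivity LnΩ of a mutant cycle.

    Invariant under any common rescaling of the four Kd (units cancel);
    swapping both the ligand/analog and WT/mutant axes leaves it
    unchanged, swapping only one negates it.
    """
    return float(
        np.log(cycle.kd_wt_ligand * cycle.kd_mut_analog)
        - np.log(cycle.kd_mut_ligand * cycle.kd_wt_analog)
    )


def coupling_energy(
    ln_omega_value: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    threshold_kT: float = SPECIFICITY_THRESHOLD_KT,
) -> CouplingResult:
    """Coupling energy |LnΩ|·kT, reported in kT multiples and kcal/mol.

    The magnitude is used for classification (cycle bar plots are
    positive-valued); the signed LnΩ is retained for interpretation.
    kcal/mol conversion uses CODATA kB and NA and the thermochemical
    calorie: |LnΩ|·kB·T·NA/4184.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    energy_kt = abs(ln_omega_value)
    kcal = energy_kt * _const.k * temperature * _const.N_A / _J_PER_KCAL
    return CouplingResult(
        ln_omega=float(ln_omega_value),
        energy_kT=float(energy_kt),
        energy_kcal_mol=float(kcal),
        temperature=float(temperature),
        is_specific=classify_specific_energy(energy_kt, threshold_kT),
        threshold_kT=threshold_kT,
    )


def classify_specific_energy(energy_kT: float, threshold_kT: float = SPECIFICITY_THRESHOLD_KT) -> bool:
    """True iff the coupling energy is strictly larger than the threshold."""
    if threshold_kT < 0:
        raise ValueError("threshold must be >= 0")
    return bool(energy_kT > threshold_kT)


def classify_specific(result: CouplingResult, threshold_kT: float = SPECIFICITY_THRESHOLD_KT) -> bool:
    """Classify a CouplingResult against the (strict) specificity threshold."""
    return classify_specific_energy(result.energy_kT, threshold_kT)
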