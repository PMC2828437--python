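"""Thermodynamic constants and IC50 <-> free-energy conversions.

Experimental affinities from competition assays are reported as IC50
concentrations.  Under the low-label assumption of the Cheng-Prusoff
relation (labelled concentration comparable to its dissociation constant),
K_i is approximated by IC50 and converted to a binding free energy

    dG_exp = -kT * ln(IC50 [molar])

so that dG_exp is positive for sub-molar IC50 and *larger means stronger
binding*.  kT defaults to 0.586 kcal/mol (room temperature).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant times room temperature, kcal/mol.
KT_ROOM_KCAL_MOL: float = 0.586

NM_PER_MOLAR: float = 1e9


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic configuration: kT in kcal/mol (must be positive)."""

    kT: float = KT_ROOM_KCAL_MOL

    def __post_init__(self) -> None:
        if not self.kT > 0:
            raise ValueError(f"kT must be positive, got {self.kT}")


DEFAULT_THERMO = ThermoParams()


def ic50_to_affinity(ic50_molar: float, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Convert an IC50 in molar units to dG_exp = -kT ln(IC50), kcal/mol."""
    if not ic50_molar > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_molar}")
    return -thermo.kT * math.log(ic50_molar)


def affinity_to_ic50(dg: float, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Inverse of :func:`ic50_to_affinity`: IC50 in molar units."""
    return math.exp(-dg / thermo.kT)


def ic50_nM_to_affinity(ic50_nM: float, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Convert an IC50 in nM (the file/IEDB convention) to kcal/mol."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return ic50_to_affinity(ic50_nM / NM_PER_MOLAR, thermo)


def affinity_to_ic50_nM(dg: float, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Convert kcal/mol back to an IC50 in nM."""
    return affinity_to_ic50(dg, thermo) * NM_PER_MOLAR


def cheng_prusoff_ki(ic50: float, labeled_conc: float, labeled_kd: float) -> float:
    """Inhibition constant K_i = IC50 / (1 + [L]/K_d).

    All three concentrations share one (arbitrary) unit; the result is in
    that same unit.  The default analysis path uses K_i ~ IC50 (valid when
    the labelled-peptide concentration is at or below its K_d); this exact
    form is provided for completeness.
    """
    for name, value in (("ic50", ic50), ("labeled_conc", labeled_conc), ("labeled_kd", labeled_kd)):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")
    return ic50 / (1.0 + labeled_conc / labeled_kd)
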