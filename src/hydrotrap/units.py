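"""Unit conventions and conversions used throughout the package.

All energies are expressed in units of the thermal energy k_BT (i.e.
k_BT == 1); absolute temperature never enters any formula.  The single
place where Joules appear is the conversion between the trap-energy
density ``epsilon`` (J/m^2, the unit in which shear-stress integrals are
naturally expressed) and hydrodynamic areas (nm^2), which requires the
numerical value of k_BT at the experimental temperature.

Conventions
-----------
* lengths: nm for molecular dimensions, um for microscope coordinates
* areas: nm^2
* surface concentrations: molecules / um^2
* trap-energy density epsilon: J/m^2
* energies: k_BT
"""

#: thermal energy at room temperature (T = 297.8 K), in Joules
KBT_J = 4.11e-21

#: nm^2 per m^2
NM2_PER_M2 = 1e18

#: um^2 per nm^2
UM2_PER_NM2 = 1e-6


def area_energy_to_kbt(area_nm2: float, epsilon_jm2: float) -> float:
    """Energy (k_BT) of a molecule of hydrodynamic area ``area_nm2`` [nm^2]
    at trap-energy density ``epsilon_jm2`` [J/m^2]."""
    return area_nm2 / NM2_PER_M2 * epsilon_jm2 / KBT_J


def slope_to_area_nm2(slope_per_jm2: float) -> float:
    """Convert a d(ln c)/d(epsilon) slope [(J/m^2)^-1] to an area [nm^2].

    The low-coverage interaction curve has slope A_hydro(0)/k_BT, so the
    area is slope * k_BT, converted from m^2 to nm^2.
    """
    return slope_per_jm2 * KBT_J * NM2_PER_M2


def coverage_from_concentration(c_per_um2, radius_nm):
    """Surface coverage Phi = c * pi * a^2 (dimensionless).

    Parameters are a concentration in molecules/um^2 and a disk radius
    in nm; the mixed units are converted internally.
    """
    import numpy as np

    return np.asarray(c_per_um2, dtype=float) * np.pi * radius_nm**2 * UM2_PER_NM2
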