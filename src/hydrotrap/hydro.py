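"""Hydrodynamic drag on surface-anchored macromolecules.

A molecule protruding a height h_c above the membrane, approximated as a
cylinder of radius a, experiences a drag force F = A_hydro * sigma_hydro
from the wall shear stress sigma_hydro of the pipette flow.  At zero
coverage the effective hydrodynamic area follows the empirical cylinder
formula

    A_hydro(0) = (0.65*(h_c/a)^2 + 5.0*(h_c/a) + 1) * pi * a^2

which this module evaluates and inverts (the inversion gives an
*effective height* from a measured area).  The trap-energy density

    epsilon_hydro(r) = integral_r^inf sigma_hydro dr'

is the work per unit hydrodynamic area to drag a molecule from infinity
to radius r; sigma is stored as the magnitude of the inward-directed
stress so epsilon is non-negative and decreasing in r.

A parametric flow model generates physically shaped sigma(r) profiles
(amplitude linear in the applied pressure, radial scale set by pipette
tip radius and pipette-surface gap) for synthesis and testing; tabulated
sigma(r) from external flow solvers can be supplied instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MoleculeGeometry",
    "ShearProfile",
    "TrapEnergyProfile",
    "ParametricFlowModel",
    "ShieldingModel",
    "a_hydro_zero",
    "effective_height",
    "force_from_shear",
    "epsilon_from_shear",
    "a_hydro_of_coverage",
]

# coefficients of the empirical cylinder-drag area formula
_C2, _C1, _C0 = 0.65, 5.0, 1.0


@dataclass(frozen=True)
class MoleculeGeometry:
    """Cylinder approximation of a molecule: radius and height in nm."""

    a: float
    h_c: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("cylinder radius must be positive")
        if self.h_c < 0:
            raise ValueError("cylinder height must be >= 0")


def a_hydro_zero(geom: MoleculeGeometry) -> float:
    """Zero-coverage hydrodynamic area [nm^2] of a cylindrical molecule."""
    x = geom.h_c / geom.a
    return (_C2 * x**2 + _C1 * x + _C0) * np.pi * geom.a**2


def effective_height(a_hydro0: float, a: float) -> float:
    """Invert the cylinder-area formula for the height h_c [nm].

    Solves 0.65*x^2 + 5*x + 1 = A/(pi a^2) for x = h_c/a; the unique
    non-negative root of the quadratic.  Requires A >= pi a^2 (a disk of
    zero height has area exactly pi a^2).
    """
    if a <= 0:
        raise ValueError("radius must be positive")
    ratio = a_hydro0 / (np.pi * a**2)
    if ratio < _C0 - 1e-12:
        raise ValueError(
            f"A_hydro(0) = {a_hydro0} nm^2 is below the zero-height limit "
            f"pi*a^2 = {np.pi * a**2:.3g} nm^2; no real non-negative height"
        )
    disc = _C1**2 + 4.0 * _C2 * max(ratio - _C0, 0.0)
    x = (-_C1 + np.sqrt(disc)) / (2.0 * _C2)
    return float(a * x)


def force_from_shear(a_hydro_nm2: float, sigma_jm3) -> float:
    """Drag force F = A_hydro * sigma [N] for area in nm^2, stress in N/m^2."""
    if np.any(np.asarray(a_hydro_nm2) < 0):
        raise ValueError("hydrodynamic area must be >= 0")
    return a_hydro_nm2 * 1e-18 * sigma_jm3


@dataclass(frozen=True)
class ShearProfile:
    """Wall shear-stress magnitude [N/m^2] on a radial grid [um]."""

    r: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "sigma", s)
        if r.ndim != 1 or r.shape != s.shape:
            raise ValueError("r and sigma must be aligned 1D arrays")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial grid must be strictly increasing")


@dataclass(frozen=True)
class TrapEnergyProfile:
    """Trap-energy density epsilon_hydro [J/m^2] on a radial grid [um]."""

    r: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        e = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "epsilon", e)
        if r.ndim != 1 or r.shape != e.shape:
            raise ValueError("r and epsilon must be aligned 1D arrays")
        if np.any(np.diff(r) <= 0):
            raise ValueError("radial grid must be strictly increasing")
        if np.any(e < -1e-15):
            raise ValueError("epsilon must be non-negative")

    def at(self, r_um):
        """Linear interpolation of epsilon onto new radii (0 outside)."""
        return np.interp(np.asarray(r_um, dtype=float), self.r, self.epsilon,
                         left=float(self.epsilon[0]), right=0.0)

    @property
    def max(self) -> float:
        return float(np.max(self.epsilon))


def epsilon_from_shear(profile: ShearProfile) -> TrapEnergyProfile:
    """Integrate the shear stress from the outer edge inward.

    epsilon(r) = integral_r^R sigma dr' (trapezoid rule on the supplied
    grid, r converted from um to m so epsilon lands in J/m^2).  Warns if
    the profile is truncated before sigma has decayed below 1e-3 of its
    peak, since the tail then carries unaccounted trap energy.
    """
    peak = float(np.max(np.abs(profile.sigma)))
    if peak > 0 and abs(profile.sigma[-1]) >= 1e-3 * peak:
        warnings.warn(
            "shear profile truncated before decaying to <1e-3 of its peak; "
            "epsilon is underestimated near the outer edge",
            stacklevel=2,
        )
    r_m = profile.r * 1e-6
    # cumulative integral from the outer edge inward
    seg = 0.5 * (profile.sigma[1:] + profile.sigma[:-1]) * np.diff(r_m)
    eps = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return TrapEnergyProfile(profile.r, np.maximum(eps, 0.0))


@dataclass(frozen=True)
class ParametricFlowModel:
    """Parametric radial stress kernel of a pipette trap.

    sigma(r) = sigma0 * (r/w) * exp(-r^2 / (2 w^2)), with radial scale
    w = tip_radius + gap (the stress vanishes at the stagnation point
    under the pipette mouth, peaks near the tip rim, and decays outward)
    and amplitude sigma0 = alpha * |delta_p| * tip_radius / w, linear in
    the applied pressure as for Stokes flow.  The closed-form trap energy
    is epsilon(r) = sigma0 * w * exp(-r^2/(2 w^2)) (w in meters).

    This is a documented stand-in family for flow-solver output, built to
    generate physically shaped trap profiles; tabulated sigma(r) input is
    the escape hatch for users with real solver results.
    """

    tip_radius_um: float = 1.0
    gap_um: float = 2.0
    delta_p_kpa: float = -9.7
    alpha: float = 0.01

    def __post_init__(self):
        if self.tip_radius_um <= 0 or self.gap_um <= 0:
            raise ValueError("pipette geometry parameters must be positive")
        if self.alpha <= 0:
            raise ValueError("shape coefficient alpha must be positive")

    @property
    def w_um(self) -> float:
        return self.tip_radius_um + self.gap_um

    @property
    def sigma0(self) -> float:
        """Stress amplitude [N/m^2]."""
        return self.alpha * abs(self.delta_p_kpa) * 1e3 * self.tip_radius_um / self.w_um

    def shear(self, r_um) -> np.ndarray:
        r = np.asarray(r_um, dtype=float)
        x = r / self.w_um
        return self.sigma0 * x * np.exp(-0.5 * x**2)

    def epsilon(self, r_um) -> np.ndarray:
        """Closed-form epsilon_hydro [J/m^2] (exact integral of the kernel)."""
        r = np.asarray(r_um, dtype=float)
        x = r / self.w_um
        return self.sigma0 * self.w_um * 1e-6 * np.exp(-0.5 * x**2)

    def shear_profile(self, r_max_um: float = 20.0, n: int = 400) -> ShearProfile:
        r = np.linspace(0.0, r_max_um, n)
        return ShearProfile(r, self.shear(r))

    def energy_profile(self, r_max_um: float = 20.0, n: int = 400) -> TrapEnergyProfile:
        r = np.linspace(0.0, r_max_um, n)
        return TrapEnergyProfile(r, self.epsilon(r))

    def scaled_to_max_epsilon(self, eps_max_jm2: float) -> "ParametricFlowModel":
        """Rescale alpha so the peak trap-energy density equals eps_max."""
        factor = eps_max_jm2 / float(self.epsilon(0.0))
        return ParametricFlowModel(
            self.tip_radius_um, self.gap_um, self.delta_p_kpa, self.alpha * factor
        )


@dataclass(frozen=True)
class ShieldingModel:
    """Coverage attenuation of the hydrodynamic area.

    Crowded molecules shield each other from the flow, so A_hydro falls
    with coverage: A(Phi) = A(0) * g(Phi).  The default family is
    g(Phi) = (1 - Phi)^nu with nu >= 0 (nu = 0 disables shielding);
    g(0) = 1 and g is monotone non-increasing on [0, 1).
    """

    form: str = "power"
    nu: float = 1.0

    def __post_init__(self):
        if self.form not in ("power", "none"):
            raise ValueError(f"unknown shielding form {self.form!r}")
        if self.nu < 0:
            raise ValueError("shielding exponent nu must be >= 0")

    def g(self, phi):
        phi_arr = np.asarray(phi, dtype=float)
        if np.any(phi_arr < 0) or np.any(phi_arr >= 1):
            raise ValueError("coverage must satisfy 0 <= phi < 1")
        if self.form == "none":
            out = np.ones_like(phi_arr)
        else:
            out = (1.0 - phi_arr) ** self.nu
        return out if np.ndim(phi) else float(out)


def a_hydro_of_coverage(a_hydro0: float, phi, shielding: ShieldingModel | None = None):
    """Coverage-dependent hydrodynamic area A(Phi) = A(0) * g(Phi) [nm^2]."""
    if shielding is None:
        shielding = ShieldingModel()
    return a_hydro0 * shielding.g(phi)
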