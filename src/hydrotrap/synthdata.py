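"""Ground-truth synthetic trapping datasets.

Generates everything the measurement pipeline consumes — trap-energy
profiles, steady-state concentration profiles for a chosen interaction
model, and noisy rendered camera images — from a fully recorded
GroundTruth description, so parameter recovery can be tested end to end
without any experimental data.

The steady state obeys the force balance d(mu)/d(r) = A_hydro * sigma,
i.e. d(mu)/d(epsilon) = A_hydro(c): the concentration profile is the
solution of that ODE up the trap-energy axis, starting from the ambient
density c0 where the trap energy vanishes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from . import units
from .hydro import (
    MoleculeGeometry,
    ParametricFlowModel,
    ShieldingModel,
    TrapEnergyProfile,
    a_hydro_zero,
)
from .pipeline import RadialProfile, TrapImage, IntensityCalibration
from .thermo import HardDiskModel

__all__ = [
    "NoiseSpec",
    "ImageGeometry",
    "GroundTruth",
    "forward_steady_state",
    "render_image",
    "make_scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Camera noise: Poisson counting noise plus Gaussian read noise.

    ``enabled=False`` renders an exact noiseless image.  There is no
    optical blur by default — trap features span many pixels — but a
    Gaussian PSF of width ``blur_px`` can be switched on for robustness
    testing.
    """

    enabled: bool = True
    read_noise: float = 2.0
    blur_px: float = 0.0


@dataclass(frozen=True)
class ImageGeometry:
    """Rendered frame: square n_px image at pixel_size um/px."""

    n_px: int = 512
    pixel_size_um: float = 0.22


@dataclass
class GroundTruth:
    """Complete description of one synthetic trapping experiment.

    mu_model: a HardDiskModel, None (ideal, non-interacting), or
        ("linear", radius_nm, slope) — an excess chemical potential
        linear in coverage, the shape simulated rotating rods produce.
    a_hydro0: zero-coverage hydrodynamic area [nm^2].
    shielding: coverage attenuation of A_hydro (None disables).
    shielding_radius_nm: radius defining the coverage fed to the
        shielding model (defaults to the mu model's radius).
    c0: ambient surface density [molecules/um^2].
    flow: parametric flow model providing epsilon_hydro(r).
    calibration: forward imaging model (intensity per molecule,
        background) reused by the pipeline when analysing the render.
    coverage_cap: generation aborts with the saturating radius reported
        if the coverage would exceed this physical cap.
    """

    mu_model: object = None
    a_hydro0: float = 296.0
    shielding: ShieldingModel | None = field(default_factory=ShieldingModel)
    shielding_radius_nm: float | None = None
    c0: float = 300.0
    flow: ParametricFlowModel = field(
        default_factory=lambda: ParametricFlowModel().scaled_to_max_epsilon(1e-4)
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    image: ImageGeometry = field(default_factory=ImageGeometry)
    calibration: IntensityCalibration = field(
        default_factory=lambda: IntensityCalibration(intensity_per_molecule=4.0, background=100.0)
    )
    seed: int = 0
    name: str = "custom"
    coverage_cap: float = 0.5

    def mu_radius(self) -> float | None:
        if isinstance(self.mu_model, HardDiskModel):
            return self.mu_model.a_hd
        if isinstance(self.mu_model, tuple) and self.mu_model[0] == "linear":
            return float(self.mu_model[1])
        return None

    def metadata(self) -> dict:
        mu = self.mu_model
        if isinstance(mu, HardDiskModel):
            mu_desc = {"kind": "hard_disk", **asdict(mu)}
        elif isinstance(mu, tuple):
            mu_desc = {"kind": mu[0], "radius_nm": mu[1], "slope_kBT_per_phi": mu[2]}
        else:
            mu_desc = {"kind": "ideal"}
        return {
            "name": self.name,
            "mu_model": mu_desc,
            "a_hydro0_nm2": self.a_hydro0,
            "shielding": None if self.shielding is None else asdict(self.shielding),
            "shielding_radius_nm": self.shielding_radius_nm,
            "c0_per_um2": self.c0,
            "flow": asdict(self.flow),
            "noise": asdict(self.noise),
            "image": asdict(self.image),
            "calibration": asdict(self.calibration),
            "seed": self.seed,
            "coverage_cap": self.coverage_cap,
        }

    def to_json(self) -> str:
        return json.dumps(self.metadata(), indent=1, sort_keys=True)


def _mu_ex_and_derivative(truth: GroundTruth):
    """(mu_ex(c), d mu_ex/dc) [k_BT, k_BT um^2] for the truth's model."""
    mu = truth.mu_model
    if mu is None:
        return (lambda c: 0.0), (lambda c: 0.0)
    if isinstance(mu, HardDiskModel):
        a_c = np.pi * mu.a_hd**2 * units.UM2_PER_NM2

        def mu_ex(c):
            phi = min(c * a_c, 0.999)
            return 2 * mu.B2 * phi + 1.5 * mu.B3 * phi**2 + (4 / 3) * mu.B4 * phi**3

        def dmu(c):
            phi = min(c * a_c, 0.999)
            return (2 * mu.B2 + 3 * mu.B3 * phi + 4 * mu.B4 * phi**2) * a_c

        return mu_ex, dmu
    if isinstance(mu, tuple) and mu[0] == "linear":
        _, radius, slope = mu
        a_c = np.pi * radius**2 * units.UM2_PER_NM2
        return (lambda c: slope * c * a_c), (lambda c: slope * a_c)
    raise TypeError(f"unsupported mu model: {mu!r}")


def forward_steady_state(
    truth: GroundTruth, r_um: np.ndarray | None = None
) -> RadialProfile:
    """Steady-state concentration profile c(r) [molecules/um^2].

    Solves (1/c + d mu_ex/dc) dc/d(eps) = A_hydro(c)/k_BT from the far
    field inward; c is non-increasing in r and approaches c0 where the
    trap energy vanishes.  Raises with the saturating radius if the
    coverage cap is exceeded (the virial model is not trustworthy toward
    close packing).
    """
    if r_um is None:
        half = truth.image.n_px * truth.image.pixel_size_um / 2.0
        r_um = np.linspace(0.0, np.sqrt(2.0) * half, 400)
    r_um = np.asarray(r_um, dtype=float)
    mu_ex, dmu = _mu_ex_and_derivative(truth)

    shield_radius = truth.shielding_radius_nm or truth.mu_radius()
    if truth.shielding is not None and shield_radius is not None:
        a_s = np.pi * shield_radius**2 * units.UM2_PER_NM2

        def area(c):
            return truth.a_hydro0 * truth.shielding.g(min(c * a_s, 0.999))

    else:

        def area(c):
            return truth.a_hydro0

    def rhs(_e, y):
        c = max(y[0], 1e-12)
        return [units.area_energy_to_kbt(area(c), 1.0) / (1.0 / c + dmu(c))]

    eps_r = truth.flow.epsilon(r_um)
    eps_max = float(np.max(eps_r))
    sol = solve_ivp(
        rhs,
        (0.0, eps_max if eps_max > 0 else 1e-30),
        [truth.c0],
        dense_output=True,
        rtol=1e-9,
        atol=1e-9 * truth.c0,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"steady-state integration failed: {sol.message}")
    c_r = sol.sol(eps_r)[0]

    cap_radius = truth.mu_radius() or truth.shielding_radius_nm
    if cap_radius is not None:
        phi = units.coverage_from_concentration(c_r, cap_radius)
        if np.any(phi > truth.coverage_cap):
            r_sat = float(np.max(r_um[phi > truth.coverage_cap]))
            warnings.warn(
                f"coverage exceeds the {truth.coverage_cap:.2f} cap inside r = {r_sat:.2f} um",
                stacklevel=2,
            )
    order = np.argsort(r_um)
    return RadialProfile(r_um[order], c_r[order])


def render_image(
    profile: RadialProfile,
    cal: IntensityCalibration | None = None,
    geometry: ImageGeometry | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> TrapImage:
    """Render a radially symmetric concentration profile to a camera frame.

    Pixel mean = background + c(r_pixel) * intensity_per_molecule, with
    Poisson counting noise on the mean and additive Gaussian read noise,
    clipped to the 16-bit range.  Deterministic for a given seed.
    """
    cal = cal or IntensityCalibration(intensity_per_molecule=4.0, background=100.0)
    geometry = geometry or ImageGeometry()
    noise = noise or NoiseSpec()
    if cal.intensity_per_molecule is None:
        raise ValueError("rendering requires intensity_per_molecule calibration")
    n, px = geometry.n_px, geometry.pixel_size_um
    centre = n * px / 2.0
    coords = (np.arange(n) + 0.5) * px - centre
    rr = np.hypot(coords[None, :], coords[:, None])
    if rr.max() > profile.r[-1] + 1e-9:
        raise ValueError("profile does not cover the image's radial extent")
    c = np.interp(rr, profile.r, profile.value)
    mean = cal.background + c * cal.intensity_per_molecule
    if noise.blur_px > 0:
        from scipy.ndimage import gaussian_filter

        mean = gaussian_filter(mean, noise.blur_px)
    if noise.enabled:
        rng = np.random.default_rng(seed)
        img = rng.poisson(mean).astype(float)
        img += rng.normal(0.0, noise.read_noise, size=img.shape)
    else:
        img = mean
    if np.any(mean > 65535.0):
        warnings.warn(
            "rendered intensities exceed the 16-bit range and were clipped; "
            "reduce intensity_per_molecule to keep the trap centre unsaturated",
            stacklevel=2,
        )
    img = np.clip(img, 0.0, 65535.0)
    return TrapImage(img, pixel_size_um=px)


def _preset(name: str, geom: MoleculeGeometry, mu_model, c0: float, **kw) -> GroundTruth:
    return GroundTruth(
        mu_model=mu_model,
        a_hydro0=a_hydro_zero(geom),
        c0=c0,
        name=name,
        **kw,
    )


def _flow(delta_p_kpa: float = -9.7) -> ParametricFlowModel:
    """Preset flow: amplitude calibrated so the reference pressure
    (-9.7 kPa) peaks at 1e-4 J/m^2; other pressures scale linearly."""
    ref = ParametricFlowModel(delta_p_kpa=-9.7).scaled_to_max_epsilon(1e-4)
    return ParametricFlowModel(
        ref.tip_radius_um, ref.gap_um, delta_p_kpa, ref.alpha
    )


#: Scenario presets: published structural geometries (cylinder radius and
#: height), measured hard-disk radii as interaction models, and ambient
#: densities in the experimental range.  The rotating-rod scenario uses
#: the near-linear mu_ex(Phi) shape that free-rod simulations produce
#: (unit slope at the 1 k_BT crossing coverage of a freely rotating
#: 3:1 rod, mu_ex = Phi / 0.078).
SCENARIOS = {
    "SA": dict(geom=MoleculeGeometry(2.8, 5.0), mu=HardDiskModel(3.2), c0=300.0),
    "CD2": dict(geom=MoleculeGeometry(1.5, 7.5), mu=HardDiskModel(5.3), c0=300.0),
    "CD4": dict(geom=MoleculeGeometry(1.5, 11.0), mu=HardDiskModel(3.7), c0=300.0),
    "CD45-rotating-rod": dict(
        geom=MoleculeGeometry(1.5, 15.0), mu=("linear", 3.8, 1.0 / 0.078), c0=150.0
    ),
}


def make_scenario(name: str, seed: int = 0, delta_p_kpa: float = -9.7) -> GroundTruth:
    """Fully populated GroundTruth preset for a named scenario."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        )
    s = SCENARIOS[name]
    return _preset(
        name,
        s["geom"],
        s["mu"],
        s["c0"],
        flow=_flow(delta_p_kpa),
        seed=seed,
    )
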