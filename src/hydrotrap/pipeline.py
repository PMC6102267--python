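"""From trap images to chemical potentials.

The measurement chain: a steady-state fluorescence image of molecules
accumulated by the hydrodynamic trap is radially averaged about the trap
centre, converted to a molecular surface density c(r), and paired with
the trap-energy density epsilon_hydro(r) to form the *interaction curve*
c(epsilon).  Its low-coverage slope in ln(c) is A_hydro(0)/k_BT; the
integral mu(c) = mu(c0) + int_0^eps A_hydro(c) d(eps) gives the chemical
potential, whose excess part mu_ex = mu - k_BT ln(c/c0) is fitted to
candidate interaction models (hard disks, rotating-rod simulation
curves).

A simplified two-species steady-state model (binary hard-disk mixture at
the second-virial level, optional flow shielding of the smaller species
by the larger) reproduces the qualitative ring-shaped segregation seen
when a small and a large protein are trapped together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import units
from .hydro import TrapEnergyProfile, ShieldingModel, a_hydro_of_coverage
from .thermo import (
    HardDiskModel,
    FitResult,
    mu_excess_hard_disk,
    fit_hard_disk_radius,
)

__all__ = [
    "TrapImage",
    "RadialProfile",
    "IntensityCalibration",
    "InteractionCurve",
    "find_trap_centre",
    "radial_average",
    "intensity_to_concentration",
    "build_interaction_curve",
    "slope_a_hydro0",
    "mu_from_curve",
    "fit_interaction_models",
    "two_species_steady_state",
]


@dataclass
class TrapImage:
    """Grayscale trap image with pixel size [um/px]."""

    data: np.ndarray
    pixel_size_um: float = 0.22
    reference: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("image must be 2D")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("image intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class RadialProfile:
    """Radially averaged quantity vs distance from the trap centre.

    r [um] are bin centres (strictly increasing); ``counts`` is the
    number of pixels contributing to each bin (0 allowed for profiles
    that were never binned from an image).
    """

    r: np.ndarray
    value: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
        if self.r.shape != self.value.shape or self.r.ndim != 1:
            raise ValueError("r and value must be aligned 1D arrays")
        if len(self.r) and np.any(np.diff(self.r) <= 0):
            raise ValueError("radial grid must be strictly increasing")


@dataclass(frozen=True)
class IntensityCalibration:
    """Linear intensity-to-density conversion.

    Either ``intensity_per_molecule`` (counts per molecule/um^2, the
    single-molecule calibration route) or the pair (``c0``,
    ``baseline_intensity``) anchoring the far field to a known baseline
    density must be given; ``background`` is subtracted first.
    """

    intensity_per_molecule: float | None = None
    c0: float | None = None
    baseline_intensity: float | None = None
    background: float = 0.0

    def factor(self) -> float:
        """Molecules/um^2 per background-subtracted count."""
        if self.intensity_per_molecule is not None:
            if self.intensity_per_molecule <= 0:
                raise ValueError("intensity per molecule must be positive")
            return 1.0 / self.intensity_per_molecule
        if self.c0 is not None and self.baseline_intensity is not None:
            denom = self.baseline_intensity - self.background
            if denom <= 0 or self.c0 <= 0:
                raise ValueError("baseline anchoring requires positive c0 and contrast")
            return self.c0 / denom
        raise ValueError("calibration needs intensity_per_molecule or (c0, baseline_intensity)")


@dataclass
class InteractionCurve:
    """Paired (epsilon_hydro [J/m^2], concentration [molecules/um^2])."""

    epsilon: np.ndarray
    concentration: np.ndarray
    c0: float

    def __post_init__(self):
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.epsilon.shape != self.concentration.shape or self.epsilon.ndim != 1:
            raise ValueError("epsilon and concentration must be aligned 1D arrays")
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be >= 0")
        if self.c0 <= 0:
            raise ValueError("baseline concentration must be positive")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epsilon_J_per_m2": self.epsilon, "concentration_per_um2": self.concentration}
        )


def find_trap_centre(
    image: TrapImage, quantile: float = 0.99, refine_iters: int = 3
) -> tuple[float, float]:
    """Sub-pixel trap centre [um].

    Starts from the intensity-weighted centroid of the top-quantile
    pixels, then refines it in a circular window (which, unlike the
    threshold mask, is symmetric about the current estimate and so free
    of mask-shape bias).  Requires a dominant peak: the top-quantile
    threshold must stand out from the background by at least 4 robust
    sigma, otherwise the image is considered featureless and an error is
    raised.  Pixel centres sit at (i + 0.5) * pixel_size.
    """
    data = image.data
    thresh = np.quantile(data, quantile)
    med = np.median(data)
    mad = np.median(np.abs(data - med))
    sigma = 1.4826 * mad if mad > 0 else np.std(data)
    if sigma == 0 or (thresh - med) < 4.0 * sigma:
        raise ValueError("no dominant intensity peak above background")
    mask = data >= thresh
    w = data[mask] - med
    yy, xx = np.nonzero(mask)
    cx = float(np.sum(xx * w) / np.sum(w))
    cy = float(np.sum(yy * w) / np.sum(w))
    radius = 2.0 * np.sqrt(mask.sum() / np.pi)
    X, Y = np.meshgrid(np.arange(data.shape[1]), np.arange(data.shape[0]))
    for _ in range(refine_iters):
        m = (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2
        w = np.maximum(data[m] - med, 0.0)
        if w.sum() == 0:
            break
        cx = float(np.sum(X[m] * w) / np.sum(w))
        cy = float(np.sum(Y[m] * w) / np.sum(w))
    return (cx + 0.5) * image.pixel_size_um, (cy + 0.5) * image.pixel_size_um


def radial_average(
    image: TrapImage, centre_um: tuple[float, float], bin_width_um: float | None = None
) -> RadialProfile:
    """Per-annulus mean intensity about the centre.

    Bins are annuli of constant width (default one pixel).  Pixels are
    assigned by centre distance; the profile is reported out to the
    largest radius whose annulus lies fully inside the image, and empty
    bins are dropped rather than interpolated.
    """
    ny, nx = image.data.shape
    px = image.pixel_size_um
    if bin_width_um is None:
        bin_width_um = px
    cx, cy = centre_um
    if not (0 <= cx <= nx * px and 0 <= cy <= ny * px):
        raise ValueError("centre must lie inside the image")
    x = (np.arange(nx) + 0.5) * px - cx
    y = (np.arange(ny) + 0.5) * px - cy
    rr = np.hypot(x[None, :], y[:, None])
    r_max = min(cx, nx * px - cx, cy, ny * px - cy)
    idx = np.floor(rr / bin_width_um).astype(int)
    n_bins = int(r_max / bin_width_um)
    if n_bins < 1:
        raise ValueError("centre too close to the edge for a single full annulus")
    keep = idx < n_bins
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=image.data[keep], minlength=n_bins)
    nz = counts > 0
    centres = (np.arange(n_bins) + 0.5) * bin_width_um
    return RadialProfile(centres[nz], sums[nz] / counts[nz], counts[nz])


def intensity_to_concentration(
    profile: RadialProfile, cal: IntensityCalibration
) -> RadialProfile:
    """Convert a radial intensity profile to molecules/um^2.

    c = (I - background) * factor; negative background-subtracted
    intensities are clipped to zero with a warning.
    """
    f = cal.factor()
    raw = (profile.value - cal.background) * f
    n_neg = int(np.sum(raw < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} profile bins below background were clipped to zero", stacklevel=2
        )
    return RadialProfile(profile.r, np.maximum(raw, 0.0), profile.counts)


def build_interaction_curve(
    conc: RadialProfile, eps: TrapEnergyProfile
) -> InteractionCurve:
    """Pair concentrations with trap energies radius by radius.

    epsilon is interpolated onto the concentration profile's radial bins
    (those bins carry the measurement statistics); the curve is sorted by
    increasing epsilon.  The baseline c0 is the mean concentration over
    the outermost bins where epsilon is below 2% of its peak, falling
    back to the outermost bin.
    """
    if len(conc.r) == 0:
        raise ValueError("empty concentration profile")
    lo = max(conc.r[0], eps.r[0])
    hi = min(conc.r[-1], eps.r[-1])
    if hi <= lo:
        raise ValueError("concentration and epsilon profiles have disjoint radial support")
    e = eps.at(conc.r)
    far = e <= 0.02 * max(eps.max, 1e-300)
    c0 = float(np.mean(conc.value[far])) if np.any(far) else float(conc.value[-1])
    if c0 <= 0:
        raise ValueError("baseline concentration is non-positive; check calibration")
    order = np.argsort(e, kind="stable")
    return InteractionCurve(e[order], conc.value[order], c0)


def slope_a_hydro0(
    curve: InteractionCurve,
    coverage_cutoff: float = 0.05,
    provisional_radius_nm: float | None = None,
    weights=None,
) -> FitResult:
    """A_hydro(0) [nm^2] from the low-coverage slope of ln(c) vs epsilon.

    Points with coverage Phi = c*pi*a^2 above ``coverage_cutoff`` (under
    a provisional radius; no cut if None) are excluded; the remaining
    points are fit by (optionally weighted) linear regression and the
    slope converted through k_BT to an area.  A statistically flat curve
    is flagged rather than returned as a spurious area.
    """
    keep = curve.concentration > 0
    if provisional_radius_nm is not None:
        phi = units.coverage_from_concentration(curve.concentration, provisional_radius_nm)
        keep &= phi <= coverage_cutoff
    n = int(np.sum(keep))
    if n < 4:
        raise ValueError(f"only {n} usable low-coverage points; need >= 4")
    x = curve.epsilon[keep]
    y = np.log(curve.concentration[keep])
    if np.ptp(x) <= 0:
        raise ValueError("epsilon range is degenerate")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)[keep]
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    beta, res_, rank_, sv_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
    resid = y - X @ beta
    dof = max(n - 2, 1)
    s2 = float(resid @ (w * resid)) / dof
    cov = s2 * np.linalg.inv(X.T @ W @ X)
    slope, slope_err = float(beta[0]), float(np.sqrt(cov[0, 0]))
    area = units.slope_to_area_nm2(slope)
    area_err = units.slope_to_area_nm2(slope_err)
    ok = slope > 0 and slope > 2 * slope_err
    return FitResult(
        params={"a_hydro0_nm2": area, "slope_per_jm2": slope},
        uncertainties={"a_hydro0_nm2": area_err},
        ok=bool(ok),
        message="" if ok else "slope indistinguishable from zero (flat curve)",
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


def _isotonic_decreasing(x: np.ndarray) -> np.ndarray:
    """Best non-increasing fit (pool adjacent violators on -x)."""
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=True)
    return iso.fit_transform(np.arange(len(x)), x)


def mu_from_curve(
    curve: InteractionCurve,
    a_hydro0: float,
    shielding: ShieldingModel | None = None,
    provisional_radius_nm: float | None = None,
    monotone_tolerance: float = 0.02,
):
    """Chemical potential along the interaction curve.

    mu(c) - mu(c0) = int_0^eps A_hydro(c(eps')) d(eps') (trapezoid, in
    k_BT), with A_hydro(c) = A_hydro(0) * g(Phi) under the supplied
    shielding model and a provisional disk radius for Phi (shielding is
    skipped if either is None).  The excess part subtracts the ideal
    term: mu_ex = mu - ln(c/c0), which vanishes at the baseline by
    construction.

    c(eps) must be single-valued and non-decreasing; violations beyond
    ``monotone_tolerance`` (relative) trigger isotonic pre-smoothing with
    a warning, and the raw concentrations are returned alongside.

    Returns a dict with epsilon, concentration (smoothed), raw
    concentration, mu [k_BT] and mu_ex [k_BT].
    """
    if len(curve.epsilon) == 0:
        raise ValueError("empty interaction curve")
    eps = curve.epsilon
    c = curve.concentration.copy()
    if eps[0] > 0:
        eps = np.concatenate([[0.0], eps])
        c = np.concatenate([[curve.c0], c])
    c_raw = c.copy()
    drops = np.diff(c)
    scale = np.maximum(c[:-1], 1e-300)
    if np.any(-drops / scale > monotone_tolerance):
        warnings.warn(
            "c(epsilon) is non-monotone beyond tolerance; applying isotonic smoothing",
            stacklevel=2,
        )
        c = _isotonic_decreasing(c)
    c = np.maximum(c, 1e-12 * curve.c0)

    if shielding is not None and provisional_radius_nm is not None:
        phi = np.clip(
            units.coverage_from_concentration(c, provisional_radius_nm), 0.0, 0.999
        )
        A = a_hydro_of_coverage(a_hydro0, phi, shielding)
    else:
        A = np.full_like(c, float(a_hydro0))
    integrand = units.area_energy_to_kbt(A, 1.0)  # kBT per (J/m^2) at each point
    mu = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(eps))])
    mu_ex = mu - np.log(c / curve.c0)
    return {
        "epsilon": eps,
        "concentration": c,
        "concentration_raw": c_raw,
        "mu": mu,
        "mu_ex": mu_ex,
    }


def fit_interaction_models(
    concentration,
    mu_ex,
    candidates: dict,
    radius_bounds: tuple[float, float] = (0.3, 50.0),
    c0: float | None = None,
) -> list[tuple[str, FitResult]]:
    """Rank candidate interaction models against a mu_ex(c) curve.

    ``candidates`` maps a name to either the string ``"hard_disk"`` or a
    simulated mu_ex(Phi) curve (an object with ``phi`` and ``mu_ex``
    arrays, e.g. a CoverageSweep).  Each candidate is fitted with a
    single scale parameter — the disk or rod cross-section radius
    mapping concentration to coverage — and candidates are ranked by
    residual norm (same relative-residual convention throughout).  When
    ``c0`` is given, model curves are referenced to the baseline
    coverage, matching mu_ex measured relative to the untrapped ambient
    state.  Candidates whose curve does not reach the coverages implied
    by the data are skipped with a reason.
    """
    c = np.asarray(concentration, dtype=float)
    mu = np.asarray(mu_ex, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 (c, mu_ex) points to rank models")
    results: list[tuple[str, FitResult]] = []
    scale = np.maximum(np.abs(mu), 0.05)
    for name, cand in candidates.items():
        if isinstance(cand, str) and cand == "hard_disk":
            try:
                fit = fit_hard_disk_radius(c, mu, radius_bounds=radius_bounds, c0=c0)
            except ValueError as e:
                fit = FitResult(ok=False, message=str(e))
            results.append((name, fit))
            continue
        phi_lib = np.asarray(cand.phi, dtype=float)
        mu_lib = np.asarray(cand.mu_ex, dtype=float)
        c_max = float(np.max(c))
        a_cap = np.sqrt(phi_lib.max() / (np.pi * c_max * units.UM2_PER_NM2))
        lo = radius_bounds[0]
        if a_cap <= lo:
            results.append(
                (name, FitResult(ok=False, message="library curve coverage range insufficient"))
            )
            continue

        def resid_of(a):
            phi = units.coverage_from_concentration(c, a)
            pred = np.interp(phi, phi_lib, mu_lib)
            if c0 is not None:
                phi0 = units.coverage_from_concentration(c0, a)
                pred = pred - np.interp(phi0, phi_lib, mu_lib)
            return (pred - mu) / scale

        from scipy.optimize import minimize_scalar

        sol = minimize_scalar(
            lambda a: float(np.sum(resid_of(a) ** 2)),
            bounds=(lo, min(a_cap, radius_bounds[1])),
            method="bounded",
        )
        a_fit = float(sol.x)
        rn = float(np.sqrt(sol.fun))
        pinned = a_fit >= 0.999 * min(a_cap, radius_bounds[1])
        results.append(
            (
                name,
                FitResult(
                    params={"radius_nm": a_fit},
                    ok=bool(sol.success and not pinned),
                    message="" if not pinned else "fit pinned at library coverage limit",
                    residual_norm=rn,
                ),
            )
        )
    results.sort(key=lambda kv: (not kv[1].ok, kv[1].residual_norm if np.isfinite(kv[1].residual_norm) else np.inf))
    return results


# ---------------------------------------------------------------------------
# two-species steady state


def _mixture_mu_ex(c1, c2, m1: HardDiskModel, m2: HardDiskModel):
    """Binary hard-disk excess chemical potentials [k_BT].

    Self interactions use the full truncated virial series in each
    species' own coverage; the cross interaction is kept at the
    second-virial level with B2_cross = pi (a1 + a2)^2 / 2 (half the
    mutual exclusion area), consistent with the one-component series
    whose B2 = 2 corresponds to pi (2a)^2 / 2 in area units.
    """
    phi1 = units.coverage_from_concentration(c1, m1.a_hd)
    phi2 = units.coverage_from_concentration(c2, m2.a_hd)
    b2_cross = np.pi * (m1.a_hd + m2.a_hd) ** 2 / 2.0 * units.UM2_PER_NM2
    mu1 = mu_excess_hard_disk(min(phi1, 0.999)) + 2.0 * b2_cross * c2
    mu2 = mu_excess_hard_disk(min(phi2, 0.999)) + 2.0 * b2_cross * c1
    return mu1, mu2


def _mixture_jacobian(c1, c2, m1: HardDiskModel, m2: HardDiskModel):
    """d(mu_i)/d(c_j) of the full mu (ideal + excess), 2x2."""
    a1 = np.pi * m1.a_hd**2 * units.UM2_PER_NM2
    a2 = np.pi * m2.a_hd**2 * units.UM2_PER_NM2
    phi1, phi2 = c1 * a1, c2 * a2
    b2_cross = np.pi * (m1.a_hd + m2.a_hd) ** 2 / 2.0 * units.UM2_PER_NM2

    def dser(phi, m):
        return 2 * m.B2 + 3 * m.B3 * phi + 4 * m.B4 * phi**2

    J = np.empty((2, 2))
    J[0, 0] = 1.0 / max(c1, 1e-300) + dser(phi1, m1) * a1
    J[0, 1] = 2.0 * b2_cross
    J[1, 0] = 2.0 * b2_cross
    J[1, 1] = 1.0 / max(c2, 1e-300) + dser(phi2, m2) * a2
    return J


def two_species_steady_state(
    models: tuple[HardDiskModel, HardDiskModel],
    a_hydro0: tuple[float, float],
    eps: TrapEnergyProfile,
    c0: tuple[float, float],
    cross_shielding: ShieldingModel | None = None,
    self_shielding: ShieldingModel | None = None,
) -> tuple[RadialProfile, RadialProfile]:
    """Steady-state radial profiles of two co-trapped species.

    Integrates the coupled force balance d(mu_i)/d(eps) = A_i(c1, c2)
    from the far field (c_i = c0_i at eps = 0) up the trap-energy axis,
    then maps the solution onto the radial grid of ``eps``.  A_i is the
    species' zero-coverage hydrodynamic area, optionally attenuated: by
    total coverage (``self_shielding``, both species) and — the
    mechanism behind the ring-shaped segregation — by the *larger*
    species' local coverage acting on the smaller one
    (``cross_shielding``).

    The mixture chemical potential is the binary hard-disk model of
    :func:`_mixture_mu_ex`; this level of theory is qualitative and is
    exercised on orderings and limiting cases, not quantitative fits.

    Species with c0 = 0 are carried as exactly zero and the other
    species reduces to its single-species solution.
    """
    m1, m2 = models
    A10, A20 = a_hydro0
    c01, c02 = c0
    if c01 < 0 or c02 < 0:
        raise ValueError("baseline concentrations must be >= 0")
    if c01 == 0 and c02 == 0:
        raise ValueError("at least one species must be present")
    small_idx = 0 if m1.a_hd <= m2.a_hd else 1

    area1 = np.pi * m1.a_hd**2 * units.UM2_PER_NM2
    area2 = np.pi * m2.a_hd**2 * units.UM2_PER_NM2

    def areas(c1, c2):
        phi1, phi2 = c1 * area1, c2 * area2
        phi_tot = min(phi1 + phi2, 0.999)
        A1, A2 = A10, A20
        if self_shielding is not None:
            g = self_shielding.g(phi_tot)
            A1, A2 = A1 * g, A2 * g
        if cross_shielding is not None:
            phi_large = min(phi2 if small_idx == 0 else phi1, 0.999)
            g_cross = cross_shielding.g(phi_large)
            if small_idx == 0:
                A1 = A1 * g_cross
            else:
                A2 = A2 * g_cross
        return A1, A2

    present = np.array([c01 > 0, c02 > 0])

    def rhs(_eps, cvec):
        c1 = max(cvec[0], 0.0) if present[0] else 0.0
        c2 = max(cvec[1], 0.0) if present[1] else 0.0
        A1, A2 = areas(c1, c2)
        drive = np.array(
            [units.area_energy_to_kbt(A1, 1.0), units.area_energy_to_kbt(A2, 1.0)]
        )
        J = _mixture_jacobian(max(c1, 1e-12), max(c2, 1e-12), m1, m2)
        dc = np.zeros(2)
        idx = np.flatnonzero(present)
        sub = J[np.ix_(idx, idx)]
        try:
            dc[idx] = np.linalg.solve(sub, drive[idx])
        except np.linalg.LinAlgError as e:
            raise RuntimeError(f"singular mixture Jacobian at eps={_eps:.3g}") from e
        return dc

    eps_max = eps.max
    sol = solve_ivp(
        rhs,
        (0.0, eps_max),
        np.array([c01, c02], dtype=float),
        dense_output=True,
        rtol=1e-8,
        atol=1e-10 * max(c01 + c02, 1.0),
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"two-species steady-state integration failed: {sol.message}")

    e_of_r = eps.epsilon
    cvals = sol.sol(np.clip(e_of_r, 0.0, eps_max))
    p1 = RadialProfile(eps.r, np.maximum(cvals[0], 0.0))
    p2 = RadialProfile(eps.r, np.maximum(cvals[1], 0.0))
    return p1, p2
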