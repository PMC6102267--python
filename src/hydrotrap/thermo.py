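"""Two-dimensional hard-disk thermodynamics.

The thermodynamic reference model for laterally mobile membrane proteins
is a fluid of hard disks of radius ``a_hd``.  Its chemical potential is
the truncated virial series

    mu(Phi) = mu0 + ln(Phi) + 2*B2*Phi + (3/2)*B3*Phi^2 + (4/3)*B4*Phi^3

in units of k_BT, where Phi = c * pi * a_hd^2 is the surface coverage and
B2 = 2, B3 = 3.128, B4 = 4.258 are the 2D hard-disk virial coefficients.
The excess part (everything beyond the ideal ln term) is what trapping
experiments and Widom insertion measure.

This module also carries the empirical mapping between the *projected*
cross-sectional area of a glycosylated molecule and its effective
*hard-disk* area (the area of the hard disk with equal excess chemical
potential at 1 k_BT), together with its coefficient fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .units import coverage_from_concentration

__all__ = [
    "HardDiskModel",
    "CoverageSeries",
    "GlycoAreaModel",
    "FitResult",
    "mu_excess_hard_disk",
    "fit_hard_disk_radius",
    "glyco_hard_disk_area",
    "fit_glyco_coefficients",
]

#: 2D hard-disk virial coefficients (dimensionless)
B2_HARD_DISK = 2.0
B3_HARD_DISK = 3.128
B4_HARD_DISK = 4.258


@dataclass(frozen=True)
class HardDiskModel:
    """Hard-disk fluid: disk radius [nm] plus virial coefficients."""

    a_hd: float
    B2: float = B2_HARD_DISK
    B3: float = B3_HARD_DISK
    B4: float = B4_HARD_DISK
    mu0: float = 0.0

    def __post_init__(self):
        if not self.a_hd > 0:
            raise ValueError(f"disk radius must be positive, got {self.a_hd}")

    def coverage(self, c_per_um2):
        """Phi = c * pi * a_hd^2 for concentrations in molecules/um^2."""
        return coverage_from_concentration(c_per_um2, self.a_hd)

    def to_json(self) -> str:
        return json.dumps({"model": "hard_disk", **asdict(self)})


@dataclass(frozen=True)
class CoverageSeries:
    """Paired surface concentrations [molecules/um^2] and coverages Phi."""

    concentrations: np.ndarray
    coverages: np.ndarray
    c0: float

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        cov = np.asarray(self.coverages, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "coverages", cov)
        if conc.shape != cov.shape:
            raise ValueError("concentrations and coverages must align")
        if np.any(conc < 0) or np.any(cov < 0) or self.c0 < 0:
            raise ValueError("concentrations and coverages must be >= 0")

    @classmethod
    def from_model(cls, c_per_um2, model: HardDiskModel, c0: float) -> "CoverageSeries":
        c = np.asarray(c_per_um2, dtype=float)
        return cls(c, model.coverage(c), c0)


def mu_excess_hard_disk(phi, model: HardDiskModel | None = None):
    """Excess chemical potential [k_BT] of 2D hard disks at coverage ``phi``.

    Evaluates the virial series truncated after the fourth coefficient:
    mu_ex = 2*B2*Phi + (3/2)*B3*Phi^2 + (4/3)*B4*Phi^3.  Strictly
    increasing in Phi for positive coefficients, and exactly 0 at Phi=0.

    ``phi`` may be a scalar or array; values must satisfy 0 <= phi < 1.
    """
    if model is None:
        model = HardDiskModel(a_hd=1.0)
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr >= 1):
        raise ValueError("coverage must satisfy 0 <= phi < 1")
    out = (
        2.0 * model.B2 * phi_arr
        + 1.5 * model.B3 * phi_arr**2
        + (4.0 / 3.0) * model.B4 * phi_arr**3
    )
    return out if np.ndim(phi) else float(out)


def mu_hard_disk(phi, model: HardDiskModel | None = None):
    """Full chemical potential mu0 + ln(Phi) + mu_ex [k_BT] (phi > 0)."""
    if model is None:
        model = HardDiskModel(a_hd=1.0)
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr <= 0):
        raise ValueError("full chemical potential requires phi > 0")
    out = model.mu0 + np.log(phi_arr) + mu_excess_hard_disk(phi_arr, model)
    return out if np.ndim(phi) else float(out)


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``ok`` is False when the optimiser failed to converge, the solution
    pinned at a bound, or the data were degenerate; ``message`` says why.
    """

    params: dict = field(default_factory=dict)
    uncertainties: dict = field(default_factory=dict)
    ok: bool = True
    message: str = ""
    residual_norm: float = np.nan

    def to_json(self) -> str:
        d = {
            "params": self.params,
            "uncertainties": self.uncertainties,
            "ok": self.ok,
            "message": self.message,
            "residual_norm": None if np.isnan(self.residual_norm) else self.residual_norm,
        }
        return json.dumps(d)


def fit_hard_disk_radius(
    concentrations,
    mu_excess,
    radius_bounds: tuple[float, float] = (0.05, 50.0),
    weights=None,
    relative: bool = True,
    c0: float | None = None,
) -> FitResult:
    """Fit the hard-disk radius [nm] to a measured mu_ex(c) curve.

    Minimises residuals between the measured excess chemical potential
    and the virial series evaluated at Phi = c * pi * a^2.  When the
    ambient density ``c0`` is given, the model is referenced to it
    (mu_ex(c) - mu_ex(c0)), matching curves measured relative to the
    untrapped baseline.  Residuals are relative (scaled by
    max(|mu_ex|, 0.05 k_BT)) by default, optionally weighted.
    Uncertainty is the 1-sigma estimate from the Jacobian at the
    optimum.

    Degenerate inputs (all-zero curve, solution pinned at a bound,
    non-convergence) are reported through ``FitResult.ok``/``message``
    rather than silently returned.
    """
    c = np.asarray(concentrations, dtype=float)
    mu = np.asarray(mu_excess, dtype=float)
    if c.shape != mu.shape or c.ndim != 1:
        raise ValueError("concentrations and mu_excess must be 1D and aligned")
    if c.size < 4:
        raise ValueError("need at least 4 points to fit a radius")
    if np.ptp(c) <= 0:
        raise ValueError("concentration range is degenerate")
    w = np.ones_like(c) if weights is None else np.asarray(weights, dtype=float)

    if np.all(np.abs(mu) < 1e-12):
        return FitResult(ok=False, message="all-zero excess chemical potential; radius indeterminate")

    scale = np.maximum(np.abs(mu), 0.05) if relative else np.ones_like(mu)

    def resid(log_a):
        a = np.exp(log_a[0])
        phi = np.clip(coverage_from_concentration(c, a), 0.0, 0.999)
        pred = mu_excess_hard_disk(phi)
        if c0 is not None:
            phi0 = min(coverage_from_concentration(c0, a), 0.999)
            pred = pred - mu_excess_hard_disk(phi0)
        return w * (pred - mu) / scale

    lo, hi = radius_bounds
    # log-radius parameterisation keeps the search positive and well scaled
    x0 = np.array([np.log(np.sqrt(lo * hi))])
    sol = least_squares(resid, x0, bounds=(np.log(lo), np.log(hi)))
    a_fit = float(np.exp(sol.x[0]))

    if not sol.success:
        return FitResult(ok=False, message=f"optimizer failed: {sol.message}")
    rel_margin = 1e-3
    if a_fit <= lo * (1 + rel_margin) or a_fit >= hi * (1 - rel_margin):
        return FitResult(
            params={"a_hd_nm": a_fit},
            ok=False,
            message=f"radius pinned at bound [{lo}, {hi}]",
            residual_norm=float(np.linalg.norm(sol.fun)),
        )

    # 1-sigma from the Gauss-Newton covariance, propagated out of log space
    J = sol.jac
    dof = max(c.size - 1, 1)
    s2 = 2 * sol.cost / dof
    try:
        cov_log = s2 * np.linalg.inv(J.T @ J)
        sigma_a = float(np.sqrt(cov_log[0, 0]) * a_fit)
    except np.linalg.LinAlgError:
        sigma_a = np.nan
    return FitResult(
        params={"a_hd_nm": a_fit},
        uncertainties={"a_hd_nm": sigma_a},
        ok=True,
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


@dataclass(frozen=True)
class GlycoAreaModel:
    """Empirical map from normalized projected area to hard-disk area.

    A_hd(A_p) = (p1*(A_p-1)^2 + p2*(A_p-1) + 1) / (p1*(A_p-1)^2/plateau + 1)

    Both areas are normalized to the projected area of the sugar-free
    protein, so A_hd(1) = 1.  The curve grows roughly linearly at low
    glycosylation and saturates at ``plateau`` — the normalized projected
    area of a disk whose radius is the protein radius plus the sugar
    length.  On the physical domain (projected areas up to the plateau
    itself) the mapping is monotone and stays below the plateau; as a
    purely empirical form it mildly overshoots the plateau when
    extrapolated far beyond the fitted range.
    """

    p1: float = 0.66
    p2: float = 0.95
    plateau: float = 9.82


def glyco_hard_disk_area(a_projected, model: GlycoAreaModel | None = None):
    """Normalized hard-disk area for a normalized projected area >= 1."""
    if model is None:
        model = GlycoAreaModel()
    ap = np.asarray(a_projected, dtype=float)
    if np.any(ap < 1):
        raise ValueError("projected area is normalized to the sugar-free protein; must be >= 1")
    x = ap - 1.0
    out = (model.p1 * x**2 + model.p2 * x + 1.0) / (model.p1 * x**2 / model.plateau + 1.0)
    return out if np.ndim(a_projected) else float(out)


def fit_glyco_coefficients(
    a_projected, a_hard_disk, plateau: float = 9.82
) -> GlycoAreaModel:
    """Least-squares p1, p2 with the plateau held fixed.

    Raises ValueError for fewer than 3 points or an ill-conditioned fit
    (e.g. all points piled on the plateau so p2 is unidentifiable).
    """
    ap = np.asarray(a_projected, dtype=float)
    ahd = np.asarray(a_hard_disk, dtype=float)
    if ap.size < 3:
        raise ValueError("need at least 3 (projected, hard-disk) area points")
    if np.any(ap < 1):
        raise ValueError("projected areas must be >= 1")

    def f(x, p1, p2):
        m = GlycoAreaModel(p1=p1, p2=p2, plateau=plateau)
        return glyco_hard_disk_area(x, m)

    # the coefficients are only identifiable from the rising part of the
    # curve; points piled on the plateau leave p1/p2 unconstrained
    if np.sum(ahd < 0.9 * plateau) < 2:
        raise ValueError(
            "glyco coefficient fit is ill-conditioned: need at least 2 points "
            "below 90% of the plateau"
        )
    try:
        popt, pcov = curve_fit(f, ap, ahd, p0=[0.5, 1.0], maxfev=10000)
    except RuntimeError as e:
        raise ValueError(f"glyco coefficient fit did not converge: {e}") from e
    if not np.all(np.isfinite(pcov)):
        raise ValueError("glyco coefficient fit is ill-conditioned (degenerate points)")
    return GlycoAreaModel(p1=float(popt[0]), p2=float(popt[1]), plateau=plateau)
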