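"""Coverage sweeps, tilt-restraint calibration and derived observables.

A coverage sweep runs one Metropolis + Widom simulation per surface
coverage and assembles the excess-chemical-potential curve mu_ex(Phi).
Coverages are defined against the nominal chain cross-section
(Phi_raw = N pi a^2 / box area) and corrected by the factor 1.075^2
before comparison with hard-disk theory, because the soft WCA spheres
act as hard disks with a 7.5% larger radius.

The coverage where a curve crosses 1 k_BT defines the molecule's
effective hard-disk area; ratios of such coverages between a rigid and a
rotating molecule give the effective-width amplification caused by
flexibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .topology import BeadChainTopology, RestraintSpec, projected_area
from .system import SimulationBox, MCRunConfig
from .engine import run_mc, widom_mu_excess, EPS_LJ_DEFAULT, WidomEstimate

__all__ = [
    "COVERAGE_CORRECTION",
    "corrected_coverage",
    "CoverageSweep",
    "sweep_coverage",
    "coverage_at_1kT",
    "effective_width_ratio",
    "calibrate_restraint",
    "tilt_distribution",
    "glyco_area_sweep",
]

#: soft-disk to hard-disk coverage correction (7.5% larger radius)
COVERAGE_CORRECTION = 1.075 * 1.075


def corrected_coverage(raw_phi):
    """Map nominal-diameter coverage to effective hard-disk coverage."""
    raw = np.asarray(raw_phi, dtype=float)
    if np.any(raw < 0):
        raise ValueError("coverage must be >= 0")
    out = raw * COVERAGE_CORRECTION
    return out if np.ndim(raw_phi) else float(out)


@dataclass
class CoverageSweep:
    """mu_ex(Phi) curve from a series of MC runs.

    phi_raw / phi are the achieved nominal and corrected coverages;
    failed points are recorded in ``failures`` and leave gaps rather
    than aborting the sweep.
    """

    phi_raw: np.ndarray
    phi: np.ndarray
    mu_ex: np.ndarray
    stderr: np.ndarray
    n_molecules: np.ndarray
    failures: list = field(default_factory=list)
    label: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "phi_corrected": self.phi,
                "mu_excess_kBT": self.mu_ex,
                "stderr_kBT": self.stderr,
                "phi_raw": self.phi_raw,
                "n_molecules": self.n_molecules,
            }
        )


def _box_for(topology: BeadChainTopology, n_mol: int, phi_raw: float,
             min_height: float = 1.0) -> SimulationBox:
    """Square box hosting n_mol molecules at the requested raw coverage.

    Height clears the chain length plus insertion headroom.
    """
    a = topology.reference_radius
    L = math.sqrt(n_mol * math.pi * a * a / phi_raw)
    Lz = max(min_height, 2.0 * topology.chain_length + 0.5)
    return SimulationBox(L, L, Lz)


def sweep_coverage(
    topology: BeadChainTopology,
    restraint: RestraintSpec,
    phi_grid,
    config: MCRunConfig,
    n_molecules: int = 48,
    eps_lj: float = EPS_LJ_DEFAULT,
    label: str = "",
) -> CoverageSweep:
    """One Widom estimate per coverage grid point.

    The molecule count is held fixed and the (periodic) box scaled to
    realise each raw coverage, keeping statistics comparable across the
    grid.  Phi_raw = 0 points are returned exactly as (0, 0).  Per-point
    failures (e.g. unplaceable densities) are recorded and skipped.
    """
    phi_grid = np.asarray(phi_grid, dtype=float)
    rows, failures = [], []
    for k, phi_raw in enumerate(phi_grid):
        if phi_raw < 0:
            raise ValueError("coverage must be >= 0")
        if phi_raw == 0.0:
            rows.append((0.0, 0.0, 0.0, 0.0, 0))
            continue
        box = _box_for(topology, n_molecules, float(phi_raw))
        try:
            res = run_mc(
                [topology], box, restraint,
                config.with_seed(config.seed + 1000 * k),
                counts=[n_molecules], eps_lj=eps_lj,
            )
            est = widom_mu_excess(res)
            if not est.reliable:
                failures.append((float(phi_raw), est.message))
                continue
            rows.append(
                (res.phi_raw, corrected_coverage(res.phi_raw), est.mu_excess, est.stderr, n_molecules)
            )
        except RuntimeError as e:
            failures.append((float(phi_raw), str(e)))
    if not rows:
        raise RuntimeError(f"all sweep points failed: {failures}")
    arr = np.array([r[:4] for r in rows])
    order = np.argsort(arr[:, 0])
    return CoverageSweep(
        phi_raw=arr[order, 0],
        phi=arr[order, 1],
        mu_ex=arr[order, 2],
        stderr=arr[order, 3],
        n_molecules=np.array([rows[i][4] for i in order]),
        failures=failures,
        label=label or topology.name,
    )


def coverage_at_1kT(sweep: CoverageSweep, level: float = 1.0) -> float:
    """Corrected coverage where the mu_ex curve crosses ``level`` k_BT.

    Linear interpolation between the bracketing grid points; raises if
    the curve does not bracket the level.
    """
    phi, mu = sweep.phi, sweep.mu_ex
    if np.all(mu < level) or np.all(mu > level):
        raise ValueError(
            f"curve does not bracket {level} k_BT (range {mu.min():.3g}..{mu.max():.3g})"
        )
    # first upward crossing
    for i in range(len(mu) - 1):
        lo, hi = mu[i], mu[i + 1]
        if (lo - level) * (hi - level) <= 0 and lo != hi:
            return float(phi[i] + (level - lo) * (phi[i + 1] - phi[i]) / (hi - lo))
    raise ValueError("no crossing found despite bracketing; curve is pathological")


def effective_width_ratio(curve_flexible: CoverageSweep, curve_rigid: CoverageSweep) -> float:
    """Effective-width amplification of a flexible vs a rigid molecule.

    A molecule reaching mu_ex = 1 k_BT at coverage Phi* behaves like a
    hard disk of area proportional to 1/Phi* (the "hard-disk area"
    convention), so the amplification caused by rotational freedom is

        Phi*_rigid / Phi*_flexible,

    the factor by which the molecule's effective footprint on the
    surface grows.  Identical curves give exactly 1.
    """
    return coverage_at_1kT(curve_rigid) / coverage_at_1kT(curve_flexible)


def _tilt_pdf_unnorm(theta, k_f, t_top_nm):
    # restraint energy 100*k_f*(dz_nm)^2 with dz = t_top*(cos(theta)-1)
    u = 100.0 * k_f * (t_top_nm * (np.cos(theta) - 1.0)) ** 2
    return np.sin(theta) * np.exp(-np.minimum(u, 700.0))


def tilt_distribution(topology: BeadChainTopology, restraint: RestraintSpec, n: int = 4001):
    """Isolated-molecule tilt density p(theta) on [0, pi/2], normalised."""
    theta = np.linspace(0.0, np.pi / 2, n)
    if restraint.rigid:
        p = np.zeros_like(theta)
        p[0] = np.inf
        return theta, p
    t_top = float(topology.offsets[topology.top_index, 2])
    w = _tilt_pdf_unnorm(theta, restraint.k_f, t_top)
    norm = np.trapezoid(w, theta)
    return theta, w / norm


def _tilt_quantile_prob(k_f, t_top, alpha_rad):
    theta = np.linspace(0.0, np.pi / 2, 4001)
    w = _tilt_pdf_unnorm(theta, k_f, t_top)
    total = np.trapezoid(w, theta)
    inside = np.trapezoid(np.where(theta <= alpha_rad, w, 0.0), theta)
    return inside / total


def calibrate_restraint(
    topology: BeadChainTopology,
    half_angle_deg: float,
    prob: float = 0.95,
) -> RestraintSpec:
    """Spring constant k_f [k_BT/A^2] confining tilts to +-half_angle.

    Solves P(theta <= half_angle) = prob under the isolated-molecule
    tilt distribution p(theta) ~ sin(theta) exp(-u(theta)).  The mapping
    between spring constant and allowed angle depends on the chain
    length, so it is computed per topology rather than hard-coded.
    """
    if not (0 < half_angle_deg < 90):
        raise ValueError("half angle must be in (0, 90) degrees")
    t_top = float(topology.offsets[topology.top_index, 2])
    if t_top <= 0:
        raise ValueError("topology has no lever arm; tilt restraint is meaningless")
    alpha = math.radians(half_angle_deg)

    def f(log_kf):
        return _tilt_quantile_prob(10.0**log_kf, t_top, alpha) - prob

    log_kf = brentq(f, -6.0, 8.0, xtol=1e-10)
    return RestraintSpec(k_f=float(10.0**log_kf), L_max=topology.upright_top_altitude)


def glyco_area_sweep(
    sugar_counts,
    config: MCRunConfig,
    restraint: RestraintSpec | None = None,
    phi_grid=None,
    n_molecules: int = 36,
    protein_diameter: float = 0.3,
    sugar_diameter: float = 0.16,
):
    """Hard-disk area vs projected area for increasing glycosylation.

    For each sugar count the mu_ex(Phi) curve is swept and the coverage
    at 1 k_BT located; the normalized hard-disk area is the ratio of the
    sugar-free molecule's 1 k_BT coverage to the glycosylated one's
    (equal-area-at-equal-mu_ex).  Projected areas are the normalized
    circle-union cross sections.  Returns (projected, hard_disk) arrays
    aligned with ``sugar_counts``.
    """
    from .topology import glyco_topology

    if restraint is None:
        restraint = RestraintSpec(rigid=True)
    if phi_grid is None:
        phi_grid = np.array([0.02, 0.05, 0.09, 0.14, 0.19, 0.25])
    base = glyco_topology(0, protein_diameter, sugar_diameter)
    base_curve = sweep_coverage(base, restraint, phi_grid, config, n_molecules)
    phi_base = coverage_at_1kT(base_curve)
    a_proj, a_hd = [], []
    for ns in sugar_counts:
        topo = glyco_topology(int(ns), protein_diameter, sugar_diameter)
        scale = projected_area(topo, normalized=True)
        # denser molecules hit 1 kBT earlier: scan a proportionally lower grid
        grid = np.asarray(phi_grid, dtype=float) / max(scale, 1.0)
        curve = sweep_coverage(topo, restraint, grid, config, n_molecules)
        a_proj.append(scale)
        a_hd.append(phi_base / coverage_at_1kT(curve))
    return np.asarray(a_proj), np.asarray(a_hd)
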