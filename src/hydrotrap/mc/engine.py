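"""Metropolis engine and Widom insertion.

Pair interactions are a truncated and shifted Lennard-Jones potential
(WCA form): purely repulsive, zero at and beyond r = 2^(1/6) sigma_ij
with sigma_ij the contact diameter (sum of the two sphere radii).  The
repulsion strength eps_LJ sets how hard the effective disk is; the
default is calibrated so the second-virial effective hard-disk diameter
equals 1.075 sigma, matching the x1.075^2 coverage correction applied
when comparing soft-disk simulations to hard-disk theory.

One MC step is one trial move (translation along the wall or rigid
rotation about the anchoring point) of one randomly chosen molecule.
Excess chemical potentials are measured by ghost insertion: positions
uniform over the wall, orientations drawn from the isolated-molecule
Boltzmann distribution of the tilt restraint (and wall), so the estimate
tends to zero at vanishing coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .topology import BeadChainTopology, RestraintSpec
from .system import SimulationBox, MCRunConfig

__all__ = [
    "EPS_LJ_DEFAULT",
    "wca_pair_energy",
    "run_mc",
    "widom_mu_excess",
    "MCResult",
    "WidomEstimate",
    "total_energy",
]

#: repulsion strength [k_BT] whose B2-matched effective hard-disk
#: diameter is 1.075 sigma (soft disks behave as 7.5%-larger hard disks)
EPS_LJ_DEFAULT = 8.244

#: squared cutoff factor: r_c^2 = 2^(1/3) sigma^2
_CUT2 = 2.0 ** (1.0 / 3.0)

#: energy cap [k_BT]: guarantees rejection / zero Boltzmann weight
#: without propagating infinities
ENERGY_CAP = 1.0e3


def wca_pair_energy(distance, sigma_ij, eps_lj: float = EPS_LJ_DEFAULT):
    """Cut-and-shifted repulsive LJ energy [k_BT] at centre separation r.

    u(r) = 4*eps*((sigma/r)^12 - (sigma/r)^6) + eps  for r < 2^(1/6) sigma,
    0 beyond.  u(sigma) = eps; r -> 0 is capped at a large finite value so
    overlapping trial states are rejected rather than raising overflow.
    """
    r = np.asarray(distance, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        s6 = np.where(r > 0, (sigma_ij / np.maximum(r, 1e-300)) ** 6, np.inf)
        u = np.where(
            r * r < _CUT2 * sigma_ij**2,
            4.0 * eps_lj * (s6 * s6 - s6) + eps_lj,
            0.0,
        )
    u = np.minimum(np.nan_to_num(u, nan=ENERGY_CAP, posinf=ENERGY_CAP), ENERGY_CAP)
    return u if np.ndim(distance) else float(u)


@njit(cache=True)
def _pair_energy_kernel(pos_a, rad_a, pos_b, rad_b, skip_lo, skip_hi, Lx, Ly, eps_lj, cap):
    """WCA energy of sphere set A against sphere set B, minimum image in
    x/y, skipping B indices in [skip_lo, skip_hi) (the molecule's own
    spheres).  Early-exits at the cap."""
    E = 0.0
    na = pos_a.shape[0]
    nb = pos_b.shape[0]
    for i in range(na):
        xi = pos_a[i, 0]
        yi = pos_a[i, 1]
        zi = pos_a[i, 2]
        ri = rad_a[i]
        for j in range(nb):
            if skip_lo <= j < skip_hi:
                continue
            dx = xi - pos_b[j, 0]
            dx -= Lx * math.floor(dx / Lx + 0.5)
            dy = yi - pos_b[j, 1]
            dy -= Ly * math.floor(dy / Ly + 0.5)
            dz = zi - pos_b[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            sig = ri + rad_b[j]
            sig2 = sig * sig
            if r2 < _CUT2 * sig2:
                if r2 < 1e-12 * sig2:
                    return cap
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                E += 4.0 * eps_lj * (s6 * s6 - s6) + eps_lj
                if E >= cap:
                    return cap
    return E


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _ry(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rz(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class _TiltSampler:
    """Inverse-CDF sampler of the isolated-molecule tilt angle.

    p(theta) ~ sin(theta) * exp(-u_restraint(z_top(theta))) on
    [0, pi/2], with z_top evaluated for an on-axis top sphere.  Used for
    ghost-insertion orientations, making the reference state the
    isolated restrained molecule.
    """

    def __init__(self, topology: BeadChainTopology, restraint: RestraintSpec, n: int = 2000):
        self.rigid = restraint.rigid
        if self.rigid:
            return
        l_max = restraint.resolve_lmax(topology)
        t_top = topology.offsets[topology.top_index, 2]
        theta = np.linspace(0.0, np.pi / 2.0, n)
        z_top = topology.graft_altitude + t_top * np.cos(theta)
        u = np.array([restraint.energy(z, l_max) for z in z_top])
        w = np.sin(theta) * np.exp(-np.minimum(u, 700.0))
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(theta))])
        if cdf[-1] <= 0:
            # degenerate (extremely stiff spring): effectively upright
            self.rigid = True
            return
        self.cdf = cdf / cdf[-1]
        self.theta = theta

    def draw(self, rng: np.random.Generator) -> float:
        if self.rigid:
            return 0.0
        return float(np.interp(rng.random(), self.cdf, self.theta))


@dataclass
class WidomEstimate:
    """Widom-insertion excess chemical potential [k_BT]."""

    mu_excess: float
    stderr: float
    insertions: int
    reliable: bool = True
    message: str = ""


@dataclass
class MCResult:
    """Sampled states and statistics from one Metropolis run."""

    box: SimulationBox
    topologies: list
    counts: list
    restraint: RestraintSpec
    config: MCRunConfig
    graft_xy: np.ndarray          # (N, 2) final graft positions
    orientations: np.ndarray      # (N, 3, 3) final rotation matrices
    coords: np.ndarray            # (S, 3) final world sphere coordinates
    radii: np.ndarray             # (S,)
    mol_slices: np.ndarray        # (N+1,) sphere-index bounds per molecule
    acceptance: dict
    widom_means: np.ndarray       # per-sample mean ghost Boltzmann factor
    widom_insertions: int
    tilt_samples: np.ndarray      # per-sample tilt angle [rad] of molecule 0
    energy_tracked: float
    energy_recomputed: float
    phi_raw: float

    @property
    def n_molecules(self) -> int:
        return len(self.graft_xy)


def _build_flat(topologies, counts):
    """Flatten (topology, count) pairs to per-molecule/per-sphere arrays.

    An empty system (all counts zero) is allowed: Widom insertion into an
    empty box is the exact zero of the excess chemical potential.
    """
    mol_topo = []
    for topo, cnt in zip(topologies, counts):
        mol_topo += [topo] * int(cnt)
    n_mol = len(mol_topo)
    mol_slices = np.zeros(n_mol + 1, dtype=np.int64)
    for m, topo in enumerate(mol_topo):
        mol_slices[m + 1] = mol_slices[m] + topo.n_spheres
    radii = (
        np.concatenate([t.diameters / 2.0 for t in mol_topo])
        if mol_topo
        else np.zeros(0)
    )
    return mol_topo, mol_slices, radii


def _world_coords(topo: BeadChainTopology, R: np.ndarray, x: float, y: float) -> np.ndarray:
    out = topo.offsets @ R.T
    out[:, 0] += x
    out[:, 1] += y
    out[:, 2] += topo.graft_altitude
    return out


def _wall_ok(coords: np.ndarray, radii: np.ndarray) -> bool:
    return bool(np.all(coords[:, 2] >= radii - 1e-12))


def _place_initial(mol_topo, mol_slices, radii, box, rng, eps_lj):
    """Random sequential insertion of upright molecules; lattice fallback.

    Raises RuntimeError with the achievable maximum count when even the
    lattice cannot host the requested number without overlap.
    """
    n_mol = len(mol_topo)
    S = mol_slices[-1]
    coords = np.zeros((S, 3))
    graft_xy = np.zeros((n_mol, 2))
    orientations = np.tile(np.eye(3), (n_mol, 1, 1))
    placed = 0
    for m, topo in enumerate(mol_topo):
        lo, hi = mol_slices[m], mol_slices[m + 1]
        ok = False
        for _ in range(400):
            x, y = rng.random() * box.Lx, rng.random() * box.Ly
            cand = _world_coords(topo, np.eye(3), x, y)
            e = _pair_energy_kernel(
                cand, radii[lo:hi], coords[: mol_slices[placed]], radii[: mol_slices[placed]],
                -1, -1, box.Lx, box.Ly, eps_lj, ENERGY_CAP,
            )
            if e < 2.0:
                graft_xy[m] = (x, y)
                coords[lo:hi] = cand
                ok = True
                break
        if not ok:
            break
        placed += 1

    if placed == n_mol:
        return graft_xy, orientations, coords

    # lattice fallback: square grid, one molecule per site
    side = int(np.ceil(np.sqrt(n_mol)))
    sx, sy = box.Lx / side, box.Ly / side
    max_sigma = 2.0 * max(float(np.max(t.diameters)) / 2.0 for t in mol_topo)
    if min(sx, sy) < max_sigma * _CUT2**0.5:
        max_fit = int((box.Lx / (max_sigma * _CUT2**0.5)) * (box.Ly / (max_sigma * _CUT2**0.5)))
        raise RuntimeError(
            f"cannot place {n_mol} molecules without overlap; "
            f"lattice capacity of this box is ~{max_fit}"
        )
    k = 0
    for m, topo in enumerate(mol_topo):
        i, j = divmod(k, side)
        x, y = (j + 0.5) * sx, (i + 0.5) * sy
        graft_xy[m] = (x, y)
        lo, hi = mol_slices[m], mol_slices[m + 1]
        coords[lo:hi] = _world_coords(topo, np.eye(3), x, y)
        k += 1
    return graft_xy, orientations, coords


def total_energy(coords, radii, mol_slices, box, restraint, mol_topo, orientations, eps_lj=EPS_LJ_DEFAULT):
    """Fresh recomputation of the total energy [k_BT] from coordinates."""
    n_mol = len(mol_slices) - 1
    E = 0.0
    for m in range(n_mol):
        lo, hi = mol_slices[m], mol_slices[m + 1]
        E += 0.5 * _pair_energy_kernel(
            coords[lo:hi], radii[lo:hi], coords, radii, lo, hi,
            box.Lx, box.Ly, eps_lj, ENERGY_CAP,
        )
        topo = mol_topo[m]
        l_max = restraint.resolve_lmax(topo)
        E += restraint.energy(coords[lo + topo.top_index, 2], l_max)
    return E


def run_mc(
    topologies,
    box: SimulationBox,
    restraint: RestraintSpec,
    config: MCRunConfig,
    counts=None,
    eps_lj: float = EPS_LJ_DEFAULT,
) -> MCResult:
    """Metropolis-Hastings sampling of grafted bead chains.

    ``topologies`` is a single BeadChainTopology or a list; ``counts``
    the matching molecule count(s).  Moves are wall translations and
    rigid rotations about the graft point; the hard wall and (optional)
    tilt restraint act alongside the WCA pair energy.  Runs are
    reproducible bit-for-bit for a given config seed.
    """
    if isinstance(topologies, BeadChainTopology):
        topologies = [topologies]
        counts = [1 if counts is None else int(counts)]
    if counts is None:
        raise ValueError("counts required when passing a topology list")
    mol_topo, mol_slices, radii = _build_flat(topologies, counts)
    n_mol = len(mol_topo)
    rng = np.random.default_rng(config.seed)

    graft_xy, orientations, coords = _place_initial(
        mol_topo, mol_slices, radii, box, rng, eps_lj
    )

    can_rotate = (not restraint.rigid) and any(t.n_spheres > 1 for t in mol_topo)
    samplers = {id(t): _TiltSampler(t, restraint) for t in topologies}
    l_max = {id(t): restraint.resolve_lmax(t) for t in topologies}

    n_equil = int(config.n_steps * config.equilibration_fraction)
    t_amp, r_amp = config.translation_amp, config.rotation_amp
    acc = {"translation": [0, 0], "rotation": [0, 0]}
    win = {"translation": [0, 0], "rotation": [0, 0]}
    widom_means, tilt_samples = [], []
    widom_total = 0
    E_track = total_energy(coords, radii, mol_slices, box, restraint, mol_topo, orientations, eps_lj)

    phi_raw = sum(
        c * np.pi * t.reference_radius**2 for t, c in zip(topologies, counts)
    ) / box.area

    for step in range(config.n_steps):
        if n_mol == 0:
            if step >= n_equil and (step - n_equil) % config.sample_interval == 0:
                widom_means.append(1.0)
                widom_total += config.widom_per_sample
            continue
        m = int(rng.integers(n_mol))
        topo = mol_topo[m]
        lo, hi = mol_slices[m], mol_slices[m + 1]
        rotate = can_rotate and topo.n_spheres > 1 and rng.random() < config.rotation_move_fraction
        kind = "rotation" if rotate else "translation"

        e_old = _pair_energy_kernel(
            coords[lo:hi], radii[lo:hi], coords, radii, lo, hi,
            box.Lx, box.Ly, eps_lj, ENERGY_CAP,
        )
        z_top_old = coords[lo + topo.top_index, 2]
        u_old = restraint.energy(z_top_old, l_max.get(id(topo), restraint.resolve_lmax(topo)))

        if rotate:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            ang = (rng.random() * 2.0 - 1.0) * r_amp
            R_new = _rotation_matrix(v, ang) @ orientations[m]
            cand = _world_coords(topo, R_new, graft_xy[m, 0], graft_xy[m, 1])
        else:
            dx = (rng.random() * 2.0 - 1.0) * t_amp
            dy = (rng.random() * 2.0 - 1.0) * t_amp
            x = (graft_xy[m, 0] + dx) % box.Lx
            y = (graft_xy[m, 1] + dy) % box.Ly
            cand = coords[lo:hi] + np.array([x - graft_xy[m, 0], y - graft_xy[m, 1], 0.0])

        win[kind][1] += 1
        acc[kind][1] += 1
        if _wall_ok(cand, radii[lo:hi]):
            e_new = _pair_energy_kernel(
                cand, radii[lo:hi], coords, radii, lo, hi,
                box.Lx, box.Ly, eps_lj, ENERGY_CAP,
            )
            z_top_new = cand[topo.top_index, 2]
            u_new = restraint.energy(z_top_new, l_max.get(id(topo), restraint.resolve_lmax(topo)))
            dU = (e_new + u_new) - (e_old + u_old)
            if dU <= 0.0 or rng.random() < math.exp(-min(dU, 700.0)):
                coords[lo:hi] = cand
                if rotate:
                    orientations[m] = R_new
                else:
                    graft_xy[m] = (x, y)
                acc[kind][0] += 1
                win[kind][0] += 1
                E_track += dU

        # amplitude auto-tune during equilibration, frozen afterwards
        if config.autotune and step < n_equil and (step + 1) % 500 == 0:
            for key, amp_name in (("translation", "t"), ("rotation", "r")):
                tried = win[key][1]
                if tried >= 50:
                    frac = win[key][0] / tried
                    factor = 1.15 if frac > 0.5 else (0.85 if frac < 0.3 else 1.0)
                    if amp_name == "t":
                        t_amp = min(max(t_amp * factor, 1e-4), box.Lx / 2)
                    else:
                        r_amp = min(max(r_amp * factor, 1e-3), np.pi)
                win[key] = [0, 0]

        if step >= n_equil and (step - n_equil) % config.sample_interval == 0:
            R0 = orientations[0]
            tilt_samples.append(math.acos(min(max(R0[2, 2], -1.0), 1.0)))
            if config.widom_per_sample > 0:
                b_sum = 0.0
                for topo_g in [topologies[0]]:
                    sampler = samplers.get(id(topo_g)) or _TiltSampler(topo_g, restraint)
                    rad_g = topo_g.diameters / 2.0
                    for _ in range(config.widom_per_sample):
                        for _try in range(50):
                            theta = sampler.draw(rng)
                            Rg = _rz(rng.random() * 2 * np.pi) @ _ry(theta) @ _rz(rng.random() * 2 * np.pi)
                            gx, gy = rng.random() * box.Lx, rng.random() * box.Ly
                            ghost = _world_coords(topo_g, Rg, gx, gy)
                            if _wall_ok(ghost, rad_g):
                                break
                        else:
                            continue
                        dU = _pair_energy_kernel(
                            ghost, rad_g, coords, radii, -1, -1,
                            box.Lx, box.Ly, eps_lj, ENERGY_CAP,
                        )
                        b_sum += math.exp(-min(dU, 700.0))
                        widom_total += 1
                widom_means.append(b_sum / config.widom_per_sample)

    E_fresh = total_energy(coords, radii, mol_slices, box, restraint, mol_topo, orientations, eps_lj)
    acceptance = {
        k: {"accepted": v[0], "tried": v[1], "rate": (v[0] / v[1] if v[1] else np.nan)}
        for k, v in acc.items()
    }
    acceptance["translation_amp"] = t_amp
    acceptance["rotation_amp"] = r_amp
    return MCResult(
        box=box,
        topologies=list(topologies),
        counts=list(counts),
        restraint=restraint,
        config=config,
        graft_xy=graft_xy,
        orientations=orientations,
        coords=coords,
        radii=radii,
        mol_slices=mol_slices,
        acceptance=acceptance,
        widom_means=np.asarray(widom_means),
        widom_insertions=widom_total,
        tilt_samples=np.asarray(tilt_samples),
        energy_tracked=E_track,
        energy_recomputed=E_fresh,
        phi_raw=phi_raw,
    )


def _effective_sample_size(x: np.ndarray) -> float:
    """ESS from the integrated autocorrelation time of a series.

    tau = 1 + 2 * sum(rho_k) with the sum truncated at the first lag
    whose autocorrelation drops below 0.05 (initial positive sequence
    style cutoff); ESS = n / tau.
    """
    n = x.size
    if n < 4:
        return float(n)
    v = np.var(x)
    if v == 0:
        return float(n)
    xc = x - x.mean()
    tau = 1.0
    for k in range(1, n // 2):
        rho = float(np.dot(xc[:-k], xc[k:]) / ((n - k) * v))
        if rho < 0.05:
            break
        tau += 2.0 * rho
    return max(n / tau, 2.0)


def widom_mu_excess(result: MCResult) -> WidomEstimate:
    """Excess chemical potential [k_BT] from a run's ghost insertions.

    mu_ex = -ln <exp(-dU)>; the standard error accounts for the serial
    correlation of the sampled configurations through the integrated
    autocorrelation time of the per-sample means (delta method through
    the logarithm).  A run where every insertion overlapped is flagged
    unreliable and reports the resolution-limited lower bound
    ln(N_insertions).
    """
    b = result.widom_means
    n_ins = result.widom_insertions
    if b.size == 0:
        raise ValueError("run recorded no Widom samples")
    mean_b = float(np.mean(b))
    if mean_b <= 0.0:
        return WidomEstimate(
            mu_excess=float(np.log(max(n_ins, 1))),
            stderr=np.inf,
            insertions=n_ins,
            reliable=False,
            message="no successful insertions; value is a lower bound",
        )
    ess = _effective_sample_size(b)
    sd = float(np.std(b, ddof=1)) if b.size > 1 else np.inf
    se_b = sd / math.sqrt(ess)
    return WidomEstimate(
        mu_excess=-math.log(mean_b),
        stderr=se_b / mean_b,
        insertions=n_ins,
        reliable=True,
    )
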