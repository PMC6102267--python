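"""Rigid bead-chain molecule topologies and the tilt restraint.

A molecule is a fixed arrangement of spheres given in a body frame whose
origin is the centre of the grafted sphere and whose +z axis is the
chain axis when the molecule stands upright.  The graft sphere touches
the wall (its centre sits at z = diameter/2 in the world frame) and the
whole body rotates rigidly about that centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeadChainTopology",
    "RestraintSpec",
    "rod_topology",
    "glyco_topology",
    "projected_area",
]


@dataclass(frozen=True)
class BeadChainTopology:
    """Rigid sphere-chain molecule grafted to the wall.

    offsets : (n, 3) body-frame sphere centres [nm], graft sphere at the
        origin, chain axis along +z when upright.
    diameters : (n,) sphere diameters [nm].
    sugar : (n,) bool flags marking sugar spheres (False = protein).
    """

    offsets: np.ndarray
    diameters: np.ndarray
    sugar: np.ndarray = None
    graft_index: int = 0
    name: str = "chain"

    def __post_init__(self):
        off = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        dia = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        sug = (
            np.zeros(len(dia), dtype=bool)
            if self.sugar is None
            else np.asarray(self.sugar, dtype=bool)
        )
        object.__setattr__(self, "offsets", off)
        object.__setattr__(self, "diameters", dia)
        object.__setattr__(self, "sugar", sug)
        if off.shape != (len(dia), 3) or len(sug) != len(dia):
            raise ValueError("offsets, diameters and sugar flags must align")
        if len(dia) < 1:
            raise ValueError("a molecule needs at least one sphere")
        if np.any(dia <= 0):
            raise ValueError("sphere diameters must be positive")
        if not (0 <= self.graft_index < len(dia)):
            raise ValueError("graft index out of range")
        if np.any(np.abs(off[self.graft_index]) > 1e-12):
            raise ValueError("graft sphere must sit at the body-frame origin")

    @property
    def n_spheres(self) -> int:
        return len(self.diameters)

    @property
    def reference_radius(self) -> float:
        """Nominal cross-section radius [nm]: the graft-sphere radius.

        Coverages Phi = N * pi * reference_radius^2 / (Lx*Ly) are defined
        against this disk, matching the convention of normalising to the
        chain cross-section.
        """
        return float(self.diameters[self.graft_index] / 2.0)

    @property
    def graft_altitude(self) -> float:
        """World z of the graft-sphere centre (sphere touching the wall)."""
        return float(self.diameters[self.graft_index] / 2.0)

    @property
    def top_index(self) -> int:
        """Index of the sphere furthest along the chain axis."""
        return int(np.argmax(self.offsets[:, 2]))

    @property
    def upright_top_altitude(self) -> float:
        """World z [nm] of the top-sphere centre when standing upright."""
        return self.graft_altitude + float(self.offsets[self.top_index, 2])

    @property
    def chain_length(self) -> float:
        """Tip-to-wall extent [nm] when upright (top sphere surface)."""
        return self.upright_top_altitude + self.diameters[self.top_index] / 2.0

    def without_sugars(self) -> "BeadChainTopology":
        """Protein-only copy (sugar spheres stripped).

        Assumes protein spheres precede sugars, which the builders here
        guarantee, so the graft index is unchanged.
        """
        keep = ~self.sugar
        if self.sugar[self.graft_index]:
            raise ValueError("graft sphere is a sugar; cannot strip it")
        return BeadChainTopology(
            self.offsets[keep],
            self.diameters[keep],
            graft_index=self.graft_index,
            name=self.name + "-desugared",
        )


@dataclass(frozen=True)
class RestraintSpec:
    """Quadratic tilt restraint on the top sphere.

    u = k_f * (z - L_max)^2 with k_f in k_BT/Angstrom^2 and z the
    altitude of the top-sphere centre; L_max [nm] is that altitude when
    the molecule stands perpendicular to the wall, so the restraint
    energy is zero upright.  k_f = 0 leaves the molecule free to rotate
    (tilt angles up to +-90 deg, bounded by the wall); rigid=True pins it
    upright (the k_f -> infinity limit, implemented without moves).
    """

    k_f: float = 0.0
    L_max: float | None = None
    rigid: bool = False

    def __post_init__(self):
        if self.k_f < 0:
            raise ValueError("spring constant must be >= 0")

    def resolve_lmax(self, topology: BeadChainTopology) -> float:
        return self.L_max if self.L_max is not None else topology.upright_top_altitude

    def energy(self, z_top_nm: float, l_max_nm: float) -> float:
        """Restraint energy [k_BT]; 100 converts nm^2 to Angstrom^2."""
        if self.rigid or self.k_f == 0.0:
            return 0.0
        dz = z_top_nm - l_max_nm
        return 100.0 * self.k_f * dz * dz


def rod_topology(n_spheres: int = 3, diameter: float = 0.1) -> BeadChainTopology:
    """Straight stack of equal touching spheres (aspect ratio n:1)."""
    if n_spheres < 1:
        raise ValueError("need at least one sphere")
    off = np.zeros((n_spheres, 3))
    off[:, 2] = diameter * np.arange(n_spheres)
    return BeadChainTopology(
        off, np.full(n_spheres, float(diameter)), name=f"rod-{n_spheres}x{diameter}"
    )


def glyco_topology(
    n_sugars: int,
    protein_diameter: float = 0.3,
    sugar_diameter: float = 0.16,
    attachments: list[tuple[int, float]] | None = None,
) -> BeadChainTopology:
    """Model glycoprotein: three stacked protein spheres plus sugar chains.

    Each sugar is a chain of two touching spheres extending horizontally
    from the surface of a protein sphere.  ``attachments`` lists
    (protein sphere index, azimuth in degrees) per sugar.  By default
    one or two sugars lie in one plane of the molecule (azimuths 0/180
    deg on the middle sphere); larger counts distribute the sugars
    evenly in azimuth around the middle sphere, so the projected
    footprint grows with the level of glycosylation toward the
    protein-plus-sugar disk.
    """
    if n_sugars < 0:
        raise ValueError("sugar count must be >= 0")
    d_p, d_s = float(protein_diameter), float(sugar_diameter)
    off = [np.array([0.0, 0.0, i * d_p]) for i in range(3)]
    dia = [d_p] * 3
    sug = [False] * 3

    if attachments is None:
        attachments = [(1, 360.0 * k / n_sugars) for k in range(n_sugars)]
    elif len(attachments) != n_sugars:
        raise ValueError("one (sphere, azimuth) attachment per sugar")

    for sphere_idx, az_deg in attachments:
        if not (0 <= sphere_idx < 3):
            raise ValueError("sugar attachment sphere index out of range")
        az = np.deg2rad(az_deg)
        u = np.array([np.cos(az), np.sin(az), 0.0])
        z = off[sphere_idx][2]
        r1 = d_p / 2 + d_s / 2        # first sugar sphere touches the protein
        r2 = r1 + d_s                 # second touches the first
        off.append(u * r1 + np.array([0.0, 0.0, z]))
        off.append(u * r2 + np.array([0.0, 0.0, z]))
        dia += [d_s, d_s]
        sug += [True, True]

    return BeadChainTopology(
        np.array(off), np.array(dia), np.array(sug), name=f"glyco-{n_sugars}"
    )


def projected_area(
    topology: BeadChainTopology,
    include_sugars: bool = True,
    normalized: bool = False,
    radius_scale: float = 1.0,
) -> float:
    """Area [nm^2] of the union of the spheres' circular projections.

    The molecule is taken upright; each sphere projects to a circle of
    its own radius (optionally scaled) on the wall plane.  With
    ``normalized=True`` the result is divided by the projected area of
    the protein-only molecule (sugar spheres stripped), the convention
    used when mapping projected to hard-disk areas.
    """
    from shapely.geometry import Point
    from shapely.ops import unary_union

    def union_area(keep: np.ndarray) -> float:
        circles = [
            Point(x, y).buffer(radius_scale * d / 2.0, quad_segs=96)
            for (x, y, _z), d in zip(topology.offsets[keep], topology.diameters[keep])
        ]
        return float(unary_union(circles).area)

    keep = np.ones(topology.n_spheres, dtype=bool) if include_sugars else ~topology.sugar
    area = union_area(keep)
    if not normalized:
        return area
    return area / union_area(~topology.sugar)
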