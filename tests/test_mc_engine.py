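"""Metropolis engine: reproducibility, detailed balance, Widom insertion."""

import numpy as np
import pytest

from hydrotrap.mc import (
    MCRunConfig,
    RestraintSpec,
    SimulationBox,
    rod_topology,
    run_mc,
    widom_mu_excess,
)
from hydrotrap.mc.engine import MCResult, total_energy
from hydrotrap.mc.sweep import _box_for


def _quick_cfg(**kw):
    base = dict(n_steps=20_000, seed=5, sample_interval=25, widom_per_sample=10)
    base.update(kw)
    return MCRunConfig(**base)


class TestReproducibility:
    def test_seeded_runs_bit_identical(self):
        topo = rod_topology(3, 0.1)
        box = _box_for(topo, 24, 0.12)
        a = run_mc([topo], box, RestraintSpec(k_f=0.0), _quick_cfg(), counts=[24])
        b = run_mc([topo], box, RestraintSpec(k_f=0.0), _quick_cfg(), counts=[24])
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.widom_means, b.widom_means)

    def test_different_seeds_differ(self):
        topo = rod_topology(3, 0.1)
        box = _box_for(topo, 24, 0.12)
        a = run_mc([topo], box, RestraintSpec(k_f=0.0), _quick_cfg(seed=1), counts=[24])
        b = run_mc([topo], box, RestraintSpec(k_f=0.0), _quick_cfg(seed=2), counts=[24])
        assert not np.array_equal(a.coords, b.coords)


class TestEnergyBookkeeping:
    def test_no_drift(self):
        """Incrementally tracked energy equals a fresh recomputation."""
        topo = rod_topology(3, 0.1)
        box = _box_for(topo, 32, 0.2)
        res = run_mc([topo], box, RestraintSpec(k_f=5.0), _quick_cfg(), counts=[32])
        ref = max(abs(res.energy_recomputed), 1.0)
        assert abs(res.energy_tracked - res.energy_recomputed) / ref < 1e-8

    def test_far_separated_molecules_non_interacting(self):
        """Two molecules far apart: zero energy and every translation
        accepted (no pair or wall rejections)."""
        topo = rod_topology(1, 0.1)
        box = SimulationBox(50.0, 50.0, 2.0)
        cfg = _quick_cfg(n_steps=2000, translation_amp=0.05, autotune=False)
        res = run_mc([topo], box, RestraintSpec(rigid=True), cfg, counts=[2])
        assert res.energy_recomputed == 0.0
        assert res.acceptance["translation"]["rate"] == 1.0


class TestMoves:
    def test_rigid_molecule_stays_upright(self):
        topo = rod_topology(3, 0.1)
        res = run_mc(
            [topo], SimulationBox(4, 4, 2), RestraintSpec(rigid=True),
            _quick_cfg(n_steps=5000), counts=[1],
        )
        assert np.all(res.tilt_samples == 0.0)
        assert res.coords[topo.top_index, 2] == pytest.approx(topo.upright_top_altitude)

    def test_very_stiff_spring_pins_top_sphere(self):
        """k_f -> large: the top sphere altitude stays at L_max within
        thermal resolution (a few hundredths of an Angstrom)."""
        topo = rod_topology(3, 0.1)
        res = run_mc(
            [topo], SimulationBox(4, 4, 2), RestraintSpec(k_f=2e4),
            _quick_cfg(n_steps=10000), counts=[1],
        )
        lever = topo.offsets[topo.top_index, 2]
        dz = lever * (1.0 - np.cos(res.tilt_samples))
        assert dz.max() < 0.004  # nm

    def test_acceptance_in_healthy_band_after_autotune(self):
        topo = rod_topology(3, 0.1)
        box = _box_for(topo, 32, 0.15)
        cfg = _quick_cfg(n_steps=30_000, equilibration_fraction=0.3)
        res = run_mc([topo], box, RestraintSpec(k_f=0.0), cfg, counts=[32])
        for kind in ("translation", "rotation"):
            assert 0.2 < res.acceptance[kind]["rate"] < 0.8

    def test_overfull_box_reports_capacity(self):
        topo = rod_topology(1, 0.5)
        with pytest.raises(RuntimeError, match="capacity"):
            run_mc([topo], SimulationBox(1.0, 1.0, 2.0), RestraintSpec(rigid=True),
                   _quick_cfg(n_steps=10), counts=[12])


class TestWidom:
    def test_empty_box_exact_zero(self):
        topo = rod_topology(3, 0.1)
        res = run_mc([topo], SimulationBox(2, 2, 2), RestraintSpec(k_f=0.0),
                     _quick_cfg(n_steps=2000), counts=[0])
        est = widom_mu_excess(res)
        assert est.mu_excess == 0.0
        assert est.stderr == 0.0
        assert est.reliable

    def test_seed_consistency_within_errors(self):
        """Independent seeds agree within 3 combined standard errors."""
        topo = rod_topology(1, 0.1)
        box = _box_for(topo, 40, 0.1)
        ests = []
        for seed in (1, 2):
            res = run_mc([topo], box, RestraintSpec(rigid=True),
                         _quick_cfg(n_steps=40_000, seed=seed, widom_per_sample=20),
                         counts=[40])
            ests.append(widom_mu_excess(res))
        d = abs(ests[0].mu_excess - ests[1].mu_excess)
        se = np.hypot(ests[0].stderr, ests[1].stderr)
        assert d < 3 * se

    def test_hard_disk_limit(self, squat_widom_points):
        """Squat grafted spheres reproduce the hard-disk virial curve
        within 5% for coverages up to ~0.2 (after the 1.075^2
        correction)."""
        from hydrotrap.thermo import mu_excess_hard_disk

        for phi_c, mu, _se in squat_widom_points:
            assert phi_c <= 0.21
            ref = mu_excess_hard_disk(phi_c)
            assert abs(mu - ref) / ref < 0.05

    def test_zero_insertion_flagged(self):
        res = MCResult(
            box=SimulationBox(), topologies=[], counts=[], restraint=RestraintSpec(),
            config=_quick_cfg(), graft_xy=np.zeros((0, 2)),
            orientations=np.zeros((0, 3, 3)), coords=np.zeros((0, 3)),
            radii=np.zeros(0), mol_slices=np.zeros(1, dtype=int), acceptance={},
            widom_means=np.zeros(10), widom_insertions=100,
            tilt_samples=np.zeros(0), energy_tracked=0.0, energy_recomputed=0.0,
            phi_raw=0.9,
        )
        est = widom_mu_excess(res)
        assert not est.reliable
        assert "lower bound" in est.message

    def test_energy_recompute_helper(self):
        topo = rod_topology(2, 0.1)
        box = _box_for(topo, 16, 0.1)
        res = run_mc([topo], box, RestraintSpec(k_f=1.0), _quick_cfg(n_steps=3000), counts=[16])
        e = total_energy(res.coords, res.radii, res.mol_slices, res.box,
                         res.restraint, [topo] * 16, res.orientations)
        assert e == pytest.approx(res.energy_recomputed)
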