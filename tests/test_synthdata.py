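"""Ground-truth generation: steady states, rendering, scenario presets."""

import dataclasses
import json

import numpy as np
import pytest

from hydrotrap import units
from hydrotrap.hydro import ShieldingModel
from hydrotrap.pipeline import find_trap_centre, radial_average
from hydrotrap.synthdata import (
    SCENARIOS,
    GroundTruth,
    ImageGeometry,
    NoiseSpec,
    forward_steady_state,
    make_scenario,
    render_image,
)
from hydrotrap.thermo import HardDiskModel


class TestForwardSteadyState:
    def test_no_trap_keeps_baseline(self):
        truth = make_scenario("SA")
        truth = dataclasses.replace(
            truth, flow=truth.flow.scaled_to_max_epsilon(1e-30)
        )
        prof = forward_steady_state(truth, np.linspace(0, 10, 50))
        assert np.allclose(prof.value, truth.c0, rtol=1e-6)

    def test_ideal_closed_form(self):
        """Non-interacting molecules, constant area: c = c0 exp(A*eps/kBT)
        exactly."""
        truth = GroundTruth(mu_model=None, a_hydro0=300.0, shielding=None, c0=300.0)
        r = np.linspace(0, 30, 200)
        prof = forward_steady_state(truth, r)
        expected = 300.0 * np.exp(units.area_energy_to_kbt(300.0, truth.flow.epsilon(r)))
        assert np.max(np.abs(prof.value - expected) / expected) < 1e-6

    def test_monotone_non_increasing_in_r(self):
        prof = forward_steady_state(make_scenario("SA"), np.linspace(0, 30, 200))
        assert np.all(np.diff(prof.value) <= 1e-9)

    def test_coverage_cap_warning(self):
        truth = GroundTruth(mu_model=HardDiskModel(3.2), a_hydro0=296.0, c0=3000.0,
                            shielding=None)
        with pytest.warns(UserWarning, match="cap"):
            forward_steady_state(truth, np.linspace(0, 30, 100))


class TestRender:
    def test_deterministic_for_seed(self):
        prof = forward_steady_state(make_scenario("SA"), np.linspace(0, 90, 200))
        a = render_image(prof, seed=3)
        b = render_image(prof, seed=3)
        c = render_image(prof, seed=4)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_zero_concentration_pure_background(self):
        prof = type(forward_steady_state(make_scenario("SA"), np.linspace(0, 90, 50)))(
            np.linspace(0, 90, 50), np.zeros(50)
        )
        img = render_image(prof, geometry=ImageGeometry(64, 0.22), noise=NoiseSpec(enabled=False))
        assert np.allclose(img.data, 100.0)

    def test_render_measure_round_trip(self, sa_like_truth):
        """Noiseless render followed by radial averaging recovers the
        input profile within discretization error."""
        prof = forward_steady_state(sa_like_truth)
        img = render_image(prof, sa_like_truth.calibration, ImageGeometry(128, 0.22),
                          NoiseSpec(enabled=False))
        meas = radial_average(img, (128 * 0.22 / 2,) * 2)
        cal = sa_like_truth.calibration
        conc = (meas.value - cal.background) / cal.intensity_per_molecule
        expected = np.interp(meas.r, prof.r, prof.value)
        assert np.max(np.abs(conc - expected) / expected) < 0.02

    def test_noise_unbiased(self, sa_like_truth):
        """The mean over seeds of noisy renders converges to the
        noiseless image."""
        prof = forward_steady_state(sa_like_truth)
        geom = ImageGeometry(64, 0.44)
        clean = render_image(prof, geometry=geom, noise=NoiseSpec(enabled=False))
        stack = np.mean(
            [render_image(prof, geometry=geom, seed=s).data for s in range(20)], axis=0
        )
        rel = np.abs(stack - clean.data) / np.maximum(clean.data, 1.0)
        assert np.mean(rel) < 0.01

    def test_insufficient_profile_extent_rejected(self):
        from hydrotrap.pipeline import RadialProfile

        prof = RadialProfile(np.linspace(0, 1, 10), np.full(10, 5.0))
        with pytest.raises(ValueError, match="radial extent"):
            render_image(prof, geometry=ImageGeometry(512, 0.22))


class TestScenarios:
    def test_sa_preset_area(self):
        truth = make_scenario("SA")
        assert round(truth.a_hydro0) == 296
        assert truth.mu_model.a_hd == 3.2

    def test_cd4_preset_area(self):
        assert round(make_scenario("CD4").a_hydro0) == 513

    def test_all_presets_instantiate(self):
        for name in SCENARIOS:
            truth = make_scenario(name, seed=2)
            assert truth.seed == 2
            assert truth.flow.epsilon(0.0) <= 1e-4 * 2.01

    def test_unknown_scenario_lists_available(self):
        with pytest.raises(KeyError, match="SA"):
            make_scenario("not-a-protein")

    def test_metadata_round_trip(self):
        truth = make_scenario("CD2", seed=9)
        meta = json.loads(truth.to_json())
        assert meta["mu_model"]["a_hd"] == 5.3
        assert meta["seed"] == 9
        # regeneration from the recorded parameters is bit-identical
        prof1 = forward_steady_state(truth, np.linspace(0, 20, 50))
        prof2 = forward_steady_state(make_scenario("CD2", seed=9), np.linspace(0, 20, 50))
        assert np.array_equal(prof1.value, prof2.value)


class TestPipelineConsistency:
    def test_generator_pipeline_mu_round_trip(self):
        """forward_steady_state followed by the measurement chain
        reproduces the generating mu_ex within quadrature error at zero
        noise (shielding on both sides)."""
        from hydrotrap.pipeline import build_interaction_curve, mu_from_curve
        from hydrotrap.thermo import mu_excess_hard_disk
        from hydrotrap.units import coverage_from_concentration

        truth = GroundTruth(mu_model=HardDiskModel(3.2), a_hydro0=296.0,
                            shielding=ShieldingModel(), c0=300.0)
        r = np.linspace(0, 30, 500)
        prof = forward_steady_state(truth, r)
        eps = truth.flow.energy_profile(r_max_um=31)
        curve = build_interaction_curve(prof, eps)
        res = mu_from_curve(curve, truth.a_hydro0, ShieldingModel(), 3.2)
        phi = coverage_from_concentration(res["concentration"], 3.2)
        phi0 = coverage_from_concentration(curve.c0, 3.2)
        ref = mu_excess_hard_disk(np.clip(phi, 0, 0.99)) - mu_excess_hard_disk(phi0)
        sel = ref > 0.3
        assert np.max(np.abs(res["mu_ex"][sel] - ref[sel]) / ref[sel]) < 0.03
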