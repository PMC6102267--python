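"""Shared fixtures.

The expensive Monte Carlo ensembles are computed once per session and
shared between the unit tests and the acceptance checks; problem sizes
are scaled-down versions of the production settings (10^5-step runs)
with the reduced precision that implies.
"""

import numpy as np
import pytest

from hydrotrap.mc import (
    MCRunConfig,
    RestraintSpec,
    rod_topology,
    run_mc,
    sweep_coverage,
    widom_mu_excess,
    corrected_coverage,
)
from hydrotrap.mc.sweep import _box_for


@pytest.fixture(scope="session")
def squat_widom_points():
    """Widom mu_ex of squat (single-sphere) grafted molecules at three
    coverages, with the corrected coverage for each: the hard-disk-limit
    reference data."""
    topo = rod_topology(1, 0.1)
    cfg = MCRunConfig(n_steps=50_000, seed=3, sample_interval=25, widom_per_sample=20)
    out = []
    for phi_raw in (0.05, 0.10, 0.18):
        box = _box_for(topo, 48, phi_raw)
        res = run_mc([topo], box, RestraintSpec(rigid=True), cfg, counts=[48])
        est = widom_mu_excess(res)
        out.append((corrected_coverage(res.phi_raw), est.mu_excess, est.stderr))
    return out


@pytest.fixture(scope="session")
def rod_flex_curves():
    """mu_ex(Phi) sweeps of the 3:1 grafted rod: rigid upright, freely
    rotating (+-90 deg), and the soft/stiff tilt springs of the
    flexibility study.  Two seeds each, averaged downstream."""
    topo = rod_topology(3, 0.1)
    grids = {
        "rigid": [0.10, 0.14, 0.18, 0.22, 0.27],
        "free": [0.015, 0.03, 0.05, 0.07, 0.09],
        "kf5": [0.04, 0.07, 0.10, 0.13, 0.16, 0.19],
    }
    restr = {
        "rigid": RestraintSpec(rigid=True),
        "free": RestraintSpec(k_f=0.0),
        "kf5": RestraintSpec(k_f=5.0),
    }
    curves = {k: [] for k in grids}
    for seed in (11, 22):
        cfg = MCRunConfig(n_steps=100_000, seed=seed, sample_interval=40, widom_per_sample=20)
        for k in grids:
            curves[k].append(sweep_coverage(topo, restr[k], grids[k], cfg, n_molecules=40))
    return curves


@pytest.fixture(scope="session")
def glyco_sweep_points():
    """(projected, hard-disk) normalized areas from MC sweeps of the
    model glycoprotein at increasing sugar counts (reduced sampling)."""
    from hydrotrap.mc import glyco_area_sweep

    cfg = MCRunConfig(n_steps=40_000, seed=13, sample_interval=40, widom_per_sample=15)
    return glyco_area_sweep([1, 2, 4, 6], cfg, n_molecules=36)


@pytest.fixture(scope="session")
def sa_like_truth():
    """Hard-disk ground truth (streptavidin-like disk radius) at a
    baseline density low enough to expose a clean ideal-gas regime."""
    from hydrotrap.pipeline import IntensityCalibration
    from hydrotrap.synthdata import GroundTruth, ImageGeometry
    from hydrotrap.thermo import HardDiskModel

    # intensity per molecule chosen to fill the 16-bit range at the trap
    # centre, keeping annulus-averaged profile noise at the ~1% level
    return GroundTruth(
        mu_model=HardDiskModel(3.2),
        a_hydro0=296.0,
        c0=100.0,
        image=ImageGeometry(n_px=256),
        calibration=IntensityCalibration(intensity_per_molecule=6.0, background=100.0),
        seed=1,
    )


@pytest.fixture(scope="session")
def sa_like_dataset(sa_like_truth):
    """Rendered noisy image of the SA-like truth plus its exact profile."""
    from hydrotrap.synthdata import forward_steady_state, render_image

    profile = forward_steady_state(sa_like_truth)
    image = render_image(
        profile,
        sa_like_truth.calibration,
        sa_like_truth.image,
        sa_like_truth.noise,
        seed=7,
    )
    return {"truth": sa_like_truth, "profile": profile, "image": image}
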