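"""File formats: CSV curves/profiles, TIFF images, JSON reports, XYZ snapshots.

CSV files are two-column with a unit-bearing header; images are 16-bit
grayscale TIFF; Monte Carlo snapshots use a plain-text XYZ dialect whose
element field is the sphere label (P = protein, S = sugar) and whose
coordinates are in nm.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hydro import ShearProfile, TrapEnergyProfile
from .pipeline import InteractionCurve, RadialProfile, TrapImage

__all__ = [
    "read_shear_csv",
    "write_shear_csv",
    "read_epsilon_csv",
    "write_epsilon_csv",
    "read_profile_csv",
    "write_profile_csv",
    "read_curve_csv",
    "write_curve_csv",
    "read_tiff",
    "write_tiff",
    "write_xyz",
    "write_json_report",
    "config_hash",
    "load_config",
]


def _two_col(path, col_r: str, col_v: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    missing = {col_r, col_v} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}; found {list(df.columns)}")
    return df[col_r].to_numpy(float), df[col_v].to_numpy(float)


def read_shear_csv(path) -> ShearProfile:
    r, s = _two_col(path, "r_um", "sigma_N_per_m2")
    return ShearProfile(r, s)


def write_shear_csv(path, profile: ShearProfile) -> None:
    pd.DataFrame({"r_um": profile.r, "sigma_N_per_m2": profile.sigma}).to_csv(path, index=False)


def read_epsilon_csv(path) -> TrapEnergyProfile:
    r, e = _two_col(path, "r_um", "epsilon_J_per_m2")
    return TrapEnergyProfile(r, e)


def write_epsilon_csv(path, profile: TrapEnergyProfile) -> None:
    pd.DataFrame({"r_um": profile.r, "epsilon_J_per_m2": profile.epsilon}).to_csv(path, index=False)


def read_profile_csv(path, value_col: str = "concentration_per_um2") -> RadialProfile:
    r, v = _two_col(path, "r_um", value_col)
    return RadialProfile(r, v)


def write_profile_csv(path, profile: RadialProfile, value_col: str = "concentration_per_um2") -> None:
    d = {"r_um": profile.r, value_col: profile.value}
    if profile.counts is not None:
        d["n_pixels"] = profile.counts
    pd.DataFrame(d).to_csv(path, index=False)


def read_curve_csv(path) -> InteractionCurve:
    df = pd.read_csv(path)
    e, c = df["epsilon_J_per_m2"].to_numpy(float), df["concentration_per_um2"].to_numpy(float)
    c0 = float(df["c0_per_um2"].iloc[0]) if "c0_per_um2" in df.columns else float(c[np.argmin(e)])
    return InteractionCurve(e, c, c0)


def write_curve_csv(path, curve: InteractionCurve) -> None:
    df = curve.to_frame()
    df["c0_per_um2"] = curve.c0
    df.to_csv(path, index=False)


def read_tiff(path, pixel_size_um: float = 0.22) -> TrapImage:
    import tifffile

    return TrapImage(tifffile.imread(path).astype(float), pixel_size_um)


def write_tiff(path, image: TrapImage) -> None:
    import tifffile

    tifffile.imwrite(path, np.clip(image.data, 0, 65535).astype(np.uint16))


def write_xyz(path, result, comment: str = "") -> None:
    """MC snapshot in the XYZ-like dialect (label x y z, nm)."""
    labels = []
    for topo, cnt in zip(result.topologies, result.counts):
        lab = np.where(topo.sugar, "S", "P")
        labels += list(lab) * cnt
    with open(path, "w") as fh:
        fh.write(f"{len(result.coords)}\n")
        fh.write(f"{comment or 'hydrotrap MC snapshot'} seed={result.config.seed}\n")
        for lab, (x, y, z) in zip(labels, result.coords):
            fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def write_json_report(path, payload: dict, config: dict | None = None, seed=None) -> None:
    """JSON report stamped with the resolved config hash and seed."""
    out = dict(payload)
    if config is not None:
        out["config_hash"] = config_hash(config)
    if seed is not None:
        out["seed"] = seed
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> dict:
    """Run configuration from YAML (or its JSON mirror)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
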