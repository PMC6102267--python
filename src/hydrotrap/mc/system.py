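"""Simulation box and Monte Carlo run configuration."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class SimulationBox:
    """Rectangular box [nm]: periodic in x and y, hard wall at z = 0.

    The default mirrors the small-sphere systems (2 x 2 x 2 nm for
    0.1 nm spheres); larger boxes are used for glycosylated molecules.
    The z extent only needs to clear the tallest molecule plus insertion
    headroom — nothing interacts with the top face.
    """

    Lx: float = 2.0
    Ly: float = 2.0
    Lz: float = 2.0

    def __post_init__(self):
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("box lengths must be positive")

    @property
    def area(self) -> float:
        return self.Lx * self.Ly


@dataclass(frozen=True)
class MCRunConfig:
    """Metropolis run parameters.

    n_steps : total MC steps (one single-molecule trial move each).
    equilibration_fraction : leading fraction of steps discarded before
        Widom sampling; move amplitudes are auto-tuned during this phase
        (target acceptance 30-50%) and then frozen.
    sample_interval : steps between Widom sampling events.
    widom_per_sample : ghost insertions per sampling event.
    translation_amp / rotation_amp : initial move amplitudes [nm / rad].
    """

    n_steps: int = 100_000
    seed: int = 0
    equilibration_fraction: float = 0.2
    sample_interval: int = 50
    widom_per_sample: int = 20
    translation_amp: float = 0.1
    rotation_amp: float = 0.4
    autotune: bool = True
    rotation_move_fraction: float = 0.5

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not (0.0 <= self.equilibration_fraction < 1.0):
            raise ValueError("equilibration fraction must be in [0, 1)")
        if self.sample_interval < 1 or self.widom_per_sample < 0:
            raise ValueError("invalid sampling settings")

    def with_seed(self, seed: int) -> "MCRunConfig":
        return replace(self, seed=int(seed))
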